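"""Packaged fixtures and demo transcript models.

The published tables travel with the package as plain TSV: the 17-row
candidate-variant table with six-predictor verdicts, the antibody-array
signaling table with printed %CFC values, and a synthetic reconstruction of
the 28-member study pedigree with segregation genotypes for the three
followed-up variants (per-individual structure and genotypes are invented
but consistent with every published count; the files say so).

Demo transcripts are synthetic gene models whose coding sequences place the
published variants at their published CDS coordinates (c.127 on a
minus-strand 8-exon kinase model with the exon-3 donor after c.295, c.202,
c.4501), so consequence annotation can be exercised end to end without a
genome build.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .annotate import TranscriptModel, synthetic_transcript
from .arrays import ArraySpot
from .pedigree import GenotypeVector, Pedigree, read_genotypes, read_ped
from .prioritize import PredictionProfile, VariantRecord


def _data_file(name: str):
    return resources.files("pedvar").joinpath("data", name)


def load_table4_spots() -> Tuple[List[ArraySpot], Dict[Tuple[str, str], float]]:
    """The published antibody-array signaling table: spots + printed %CFC column."""
    with resources.as_file(_data_file("table4_signaling.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    spots, printed = [], {}
    for r in df.itertuples(index=False):
        spot = ArraySpot(
            target=str(r.target),
            phospho_site=str(r.phospho_site),
            control_intensity=float(r.control_intensity),
            control_error_pct=float(r.control_error_pct),
            treatment_intensity=float(r.treatment_intensity),
            treatment_error_pct=float(r.treatment_error_pct),
        )
        spots.append(spot)
        printed[spot.key] = float(r.printed_cfc)
    return spots, printed


_EFFECT_TO_CONSEQUENCE = {
    "Missense variant": "missense",
    "Stop retained variant": "stop_retained",
    "Splice region variant & intron variant": "splice_region",
}
PREDICTION_TOOLS = ("polyphen2", "variowatch", "mutationtaster", "sift", "mutation_assessor", "lrt")


def load_table2_candidates() -> Tuple[List[VariantRecord], Dict[str, PredictionProfile]]:
    """The 17 candidate variants with six-predictor verdict profiles.

    Variant ids are ``GENE:p.X`` (or ``GENE:c.X`` for the non-coding row).
    """
    with resources.as_file(_data_file("table2_candidates.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#", dtype=str)
    records: List[VariantRecord] = []
    profiles: Dict[str, PredictionProfile] = {}
    for r in df.itertuples(index=False):
        consequence = _EFFECT_TO_CONSEQUENCE[r.effect]
        label = r.hgvs_p if r.hgvs_p != "." else r.hgvs_c
        vid = f"{r.gene}:{label}"
        rec = VariantRecord(
            chrom=str(r.chrom),
            pos=int(r.pos),
            ref=r.hgvs_c[-3],
            alt=r.hgvs_c[-1],
            gene=str(r.gene),
            region="splice_region" if consequence == "splice_region" else "exonic",
            af_pop=None if r.af_1000g == "." else float(r.af_1000g),
            consequence=consequence,
            variant_id=vid,
        )
        records.append(rec)
        profiles[vid] = PredictionProfile(
            vid, {tool: getattr(r, tool) for tool in PREDICTION_TOOLS}
        )
    return records, profiles


def load_ubrs033() -> Tuple[Pedigree, Dict[str, GenotypeVector]]:
    """Synthetic reconstruction of the study family and its typed genotypes."""
    with resources.as_file(_data_file("ubrs033_synthetic.ped")) as p:
        ped = read_ped(p)
    with resources.as_file(_data_file("ubrs033_genotypes.tsv")) as p:
        genotypes = read_genotypes(p)
    return ped, genotypes


UBRS033_MARRIED_IN_AFFECTED = ("II:11", "II:12")
UBRS033_SEQUENCED = ("II:1", "II:3", "II:4", "III:3", "III:4", "I:2", "II:6", "II:7")


# ---------------------------------------------------------------------------
# Demo transcript models


def _make_cds(n_codons: int, overrides: Dict[int, str], seed: int) -> str:
    """ATG + random non-stop codons + TAA, with chosen codons overridden."""
    rng = np.random.default_rng(seed)
    stops = {"TAA", "TAG", "TGA"}
    codons = ["ATG"]
    for _ in range(n_codons - 2):
        while True:
            c = "".join("ACGT"[int(rng.integers(4))] for _ in range(3))
            if c not in stops:
                break
        codons.append(c)
    codons.append("TAA")
    for idx, codon in overrides.items():
        codons[idx - 1] = codon
    return "".join(codons)


def demo_transcripts() -> Dict[str, TranscriptModel]:
    """Three synthetic gene models placing the published variants at their
    published CDS coordinates."""
    # 322-aa kinase model: codon 43 = GGA (c.127 G), exon 3 ends at c.295,
    # 8 coding exons, minus strand to exercise strand handling.
    pbk = synthetic_transcript(
        "PBK",
        _make_cds(323, {43: "GGA"}, seed=101),
        exon_lengths=[60, 60, 175, 140, 140, 140, 140, 114],
        chrom="8",
        strand="-",
        start=27_600_000,
        intron_length=500,
    )
    # codon 68 = GCT (c.202 G>A -> p.Ala68Thr), plus strand
    ankrd36 = synthetic_transcript(
        "ANKRD36",
        _make_cds(250, {68: "GCT"}, seed=102),
        exon_lengths=[250, 250, 250],
        chrom="2",
        strand="+",
        start=97_700_000,
        intron_length=400,
    )
    # long CDS: codon 1501 = CGG (c.4501 C>T -> p.Arg1501Trp)
    sorl1 = synthetic_transcript(
        "SORL1",
        _make_cds(1534, {1501: "CGG"}, seed=103),
        exon_lengths=[767, 767, 767, 767, 767, 767],
        chrom="11",
        strand="+",
        start=121_400_000,
        intron_length=600,
    )
    return {"PBK": pbk, "ANKRD36": ankrd36, "SORL1": sorl1}
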