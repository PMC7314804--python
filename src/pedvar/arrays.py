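"""Antibody-microarray signaling analysis: global normalization, the
percent-change-from-control statistic, duplicate error ranges, and the
three-criterion hit filter.

The statistic is %CFC = 100 * (treatment - control) / control computed on
globally normalized spot intensities.  A spot is a hit when all three of the
following hold:

* ``|%CFC| >= cfc_min`` (default 60; applied to the magnitude so that
  suppressed targets count as hits),
* the sum of the two duplicate %error ranges is ``< error_factor * |%CFC|``
  (default factor 0.85),
* at least one of the two normalized intensities is ``>= intensity_min``
  (default 1,000).

%CFC is always recomputed from the intensities, never trusted from input;
rows whose printed %CFC disagrees with their printed intensities can be
flagged with :func:`check_printed_cfc`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


@dataclass
class ArraySpot:
    target: str
    phospho_site: str  # site label, or "Pan-specific"
    control_intensity: float
    control_error_pct: float
    treatment_intensity: float
    treatment_error_pct: float

    def __post_init__(self):
        if self.control_intensity <= 0 or self.treatment_intensity <= 0:
            raise ValueError(f"{self.target}: intensities must be positive")
        if self.control_error_pct < 0 or self.treatment_error_pct < 0:
            raise ValueError(f"{self.target}: error percentages must be >= 0")

    @property
    def key(self) -> Tuple[str, str]:
        return (self.target, self.phospho_site)


@dataclass
class SignalingHit:
    spot: ArraySpot
    cfc_pct: float
    pass_cfc: bool
    pass_error: bool
    pass_intensity: bool

    @property
    def is_hit(self) -> bool:
        return self.pass_cfc and self.pass_error and self.pass_intensity

    @property
    def failed_criteria(self) -> List[str]:
        out = []
        if not self.pass_cfc:
            out.append("cfc")
        if not self.pass_error:
            out.append("error_sum")
        if not self.pass_intensity:
            out.append("intensity")
        return out


def percent_cfc(control: float, treatment: float) -> float:
    """Signed percent change from control: 100 * (treatment - control) / control."""
    if control <= 0:
        raise ValueError("control intensity must be positive")
    return 100.0 * (treatment - control) / control


def spot_error_range(replicates: Sequence[float]) -> float:
    """Percent error range of replicate measurements: 100 * (max-min) / (2*mean).

    For duplicates this is the half-range expressed as a percentage of the
    mean.  Requires at least two replicates.
    """
    reps = np.asarray(list(replicates), dtype=float)
    if reps.size < 2:
        raise ValueError("error range needs at least 2 replicates")
    mean = reps.mean()
    if mean <= 0:
        raise ValueError("replicate mean must be positive")
    return float(100.0 * (reps.max() - reps.min()) / (2.0 * mean))


def global_normalize(raw: pd.DataFrame) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Scale each sample so its total spot intensity equals the across-sample mean total.

    ``raw`` is tidy: columns ``sample`` and ``intensity`` (other columns pass
    through).  Within-sample ratios are preserved.  Returns the scaled table
    and the per-sample scale factors.
    """
    if raw.empty:
        raise ValueError("empty spot table")
    if (raw["intensity"] <= 0).any():
        raise ValueError("non-positive intensity in raw table")
    totals = raw.groupby("sample")["intensity"].sum()
    target = totals.mean()
    factors = (target / totals).to_dict()
    out = raw.copy()
    out["intensity"] = out["intensity"] * out["sample"].map(factors)
    return out, factors


def hit_filter(
    spots: Iterable[ArraySpot],
    cfc_min: float = 60.0,
    error_factor: float = 0.85,
    intensity_min: float = 1000.0,
) -> List[SignalingHit]:
    """Apply the three stated criteria to every spot; %CFC is recomputed."""
    out = []
    for s in spots:
        cfc = percent_cfc(s.control_intensity, s.treatment_intensity)
        out.append(
            SignalingHit(
                spot=s,
                cfc_pct=cfc,
                pass_cfc=abs(cfc) >= cfc_min,
                pass_error=(s.control_error_pct + s.treatment_error_pct) < error_factor * abs(cfc),
                pass_intensity=max(s.control_intensity, s.treatment_intensity) >= intensity_min,
            )
        )
    return out


def check_printed_cfc(
    spots: Iterable[ArraySpot], printed_cfc: Dict[Tuple[str, str], float], tol: float = 0.01
) -> Dict[Tuple[str, str], bool]:
    """Compare recomputed %CFC against a printed column; True = consistent within tol."""
    out = {}
    for s in spots:
        printed = printed_cfc[s.key]
        out[s.key] = abs(percent_cfc(s.control_intensity, s.treatment_intensity) - printed) <= tol
    return out


def recover_planted_hits(
    hits: Iterable[SignalingHit], truth: Iterable[Tuple[str, str]]
) -> Tuple[Optional[float], float]:
    """Precision and recall of called hits against a ground-truth spot list.

    Precision is None when no hits were called (undefined); an empty truth
    list makes recall undefined and raises.
    """
    truth_set = set(truth)
    if not truth_set:
        raise ValueError("empty ground-truth hit list: recall undefined")
    called = {h.spot.key for h in hits if h.is_hit}
    tp = len(called & truth_set)
    precision = tp / len(called) if called else None
    recall = tp / len(truth_set)
    return precision, recall


# ---------------------------------------------------------------------------
# Table I/O and the duplicate-spot pipeline


def read_spot_table(path) -> List[ArraySpot]:
    """Read a spot TSV with columns target, phospho_site, control_intensity,
    control_error_pct, treatment_intensity, treatment_error_pct."""
    df = pd.read_csv(path, sep="\t")
    return [
        ArraySpot(
            target=str(r.target),
            phospho_site=str(r.phospho_site),
            control_intensity=float(r.control_intensity),
            control_error_pct=float(r.control_error_pct),
            treatment_intensity=float(r.treatment_intensity),
            treatment_error_pct=float(r.treatment_error_pct),
        )
        for r in df.itertuples(index=False)
    ]


def spots_from_replicates(tidy: pd.DataFrame, control: str, treatment: str) -> List[ArraySpot]:
    """Collapse a tidy replicate table into per-spot control/treatment records.

    ``tidy`` columns: target, phospho_site, sample, replicate, intensity
    (already globally normalized).  Intensity per sample is the replicate
    mean; the %error range comes from :func:`spot_error_range`.
    """
    spots = []
    for (target, site), grp in tidy.groupby(["target", "phospho_site"], sort=False):
        c = grp.loc[grp["sample"] == control, "intensity"].to_numpy()
        t = grp.loc[grp["sample"] == treatment, "intensity"].to_numpy()
        if len(c) < 2 or len(t) < 2:
            raise ValueError(f"spot {(target, site)} lacks duplicate measurements")
        spots.append(
            ArraySpot(
                target=target,
                phospho_site=site,
                control_intensity=float(c.mean()),
                control_error_pct=spot_error_range(c),
                treatment_intensity=float(t.mean()),
                treatment_error_pct=spot_error_range(t),
            )
        )
    return spots


def hits_to_frame(hits: Iterable[SignalingHit]) -> pd.DataFrame:
    rows = []
    for h in hits:
        rows.append(
            {
                "target": h.spot.target,
                "phospho_site": h.spot.phospho_site,
                "control_intensity": h.spot.control_intensity,
                "control_error_pct": h.spot.control_error_pct,
                "treatment_intensity": h.spot.treatment_intensity,
                "treatment_error_pct": h.spot.treatment_error_pct,
                "cfc_pct": round(h.cfc_pct, 2),
                "pass_cfc": h.pass_cfc,
                "pass_error": h.pass_error,
                "pass_intensity": h.pass_intensity,
                "is_hit": h.is_hit,
            }
        )
    return pd.DataFrame(rows)
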