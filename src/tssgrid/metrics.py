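"""TSS-interdependence metrics: the seven canonical region averages and the
eight derived log2 ratios, replicate statistics, and the replicate
concordance gate.

Region semantics (x is the offset from the upstream TSS, y from the
downstream TSS; both transcription-oriented):

* A / B — signal just downstream of the upstream TSS (0 ≤ x ≤ 200) with the
  downstream TSS distal (−20k ≤ y ≤ −10k) / at intermediate distance
  (−900 ≤ y ≤ −200).
* Af / Bf — the same two y-bands at intermediate distance from the upstream
  TSS (300 ≤ x ≤ 1k).
* C / D / E — signal just downstream of the downstream TSS (0 ≤ y ≤ 200)
  with the upstream TSS proximal (0 ≤ x ≤ 200), intermediate
  (300 ≤ x ≤ 1k), and distal (10k ≤ x ≤ 20k).

Derived ratios (reported as log2): proximal cooperativity T_C/T_E, upstream
effects T_B/T_A, downstream effects T_D/T_E, positional dominance T_E/T_A,
persistence with a distal / non-distal downstream TSS T_Af/T_A and T_Bf/T_B,
signal dominance T_Bf/T_Af, and persistence dominance — the ratio of the two
persistences (T_Bf/T_B)/(T_Af/T_A).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import PairSet
from .expansion import RegionAverage, RegionSpec, region_average

REGION_LABELS = ("A", "Af", "B", "Bf", "C", "D", "E")

#: metric name -> (numerator region, denominator region)
SIMPLE_RATIOS = {
    "proximal_cooperativity": ("C", "E"),
    "upstream_effects": ("B", "A"),
    "downstream_effects": ("D", "E"),
    "positional_dominance": ("E", "A"),
    "persistence_distal": ("Af", "A"),
    "persistence_nondistal": ("Bf", "B"),
    "signal_dominance": ("Bf", "Af"),
}

METRIC_NAMES = tuple(SIMPLE_RATIOS) + ("persistence_dominance",)


def canonical_regions() -> dict[str, RegionSpec]:
    """The seven canonical rectangles in (x, y) relative-coordinate space."""
    return {
        "A": RegionSpec(0, -20_000, 200, -10_000, "A"),
        "Af": RegionSpec(300, -20_000, 1_000, -10_000, "Af"),
        "B": RegionSpec(0, -900, 200, -200, "B"),
        "Bf": RegionSpec(300, -900, 1_000, -200, "Bf"),
        "C": RegionSpec(0, 0, 200, 200, "C"),
        "D": RegionSpec(300, 0, 1_000, 200, "D"),
        "E": RegionSpec(10_000, 0, 20_000, 200, "E"),
    }


@dataclass
class MetricsPanel:
    """The seven T region averages plus derived log2 ratios for one pair set.

    ``derived`` holds only ratios whose constituent T values are all defined
    and positive; ``reasons`` records a machine-readable reason for each
    absent ratio (no pseudocounts are ever applied).
    """

    regions: dict[str, RegionAverage]
    derived: dict[str, float]
    reasons: dict[str, str]
    pair_index: int
    stratum: str = "all"
    n_pairs: int = 0

    def t(self, label: str) -> float:
        return self.regions[label].value


def _ratio_log2(regions: Mapping[str, RegionAverage], labels: tuple[str, ...]):
    """log2 of a product/quotient; returns (value, reason)."""
    for lab in labels:
        ra = regions[lab]
        if not ra.defined:
            return None, f"undefined:T_{lab}"
        if ra.value <= 0:
            return None, f"nonpositive:T_{lab}"
    return True, ""


def derive_metrics(regions: Mapping[str, RegionAverage]):
    """Compute the eight derived log2 ratios from stored T values."""
    derived: dict[str, float] = {}
    reasons: dict[str, str] = {}
    for name, (num, den) in SIMPLE_RATIOS.items():
        ok, reason = _ratio_log2(regions, (num, den))
        if ok:
            derived[name] = math.log2(regions[num].value / regions[den].value)
        else:
            reasons[name] = reason
    ok, reason = _ratio_log2(regions, ("Bf", "B", "Af", "A"))
    if ok:
        derived["persistence_dominance"] = math.log2(
            (regions["Bf"].value / regions["B"].value)
            / (regions["Af"].value / regions["A"].value)
        )
    else:
        reasons["persistence_dominance"] = reason
    return derived, reasons


def metrics_panel(signal, pairs: PairSet) -> MetricsPanel:
    """Compute T_A..T_E, T_Af, T_Bf and the derived ratios for a pair set."""
    if len(pairs) == 0:
        raise ValueError("metrics_panel requires a non-empty pair set")
    regions = {
        label: region_average(signal, pairs, spec)
        for label, spec in canonical_regions().items()
    }
    derived, reasons = derive_metrics(regions)
    return MetricsPanel(
        regions=regions,
        derived=derived,
        reasons=reasons,
        pair_index=pairs.pair_index,
        stratum=pairs.stratum,
        n_pairs=len(pairs),
    )


# -- replicate statistics ----------------------------------------------------

@dataclass(frozen=True)
class ReplicateStat:
    """Half-sum (mean) and half-difference (noise) of the two replicates'
    log2 metric values; mean ± noise reconstructs replicate 1 / 2 exactly."""

    mean: float
    noise: float


def replicate_stats(
    panel_rep1: MetricsPanel, panel_rep2: MetricsPanel
) -> tuple[dict[str, ReplicateStat], dict[str, str]]:
    """Per-metric replicate mean and noise for two matched panels.

    For a metric with log2 values m1, m2 in the two replicates,
    mean = (m1 + m2)/2 and noise = (m1 − m2)/2.  Metrics absent in either
    replicate are reported absent with a reason.
    """
    if (panel_rep1.pair_index, panel_rep1.stratum) != (panel_rep2.pair_index, panel_rep2.stratum):
        raise ValueError("replicate panels must share pair_index and stratum")
    out: dict[str, ReplicateStat] = {}
    reasons: dict[str, str] = {}
    for name in METRIC_NAMES:
        in1 = name in panel_rep1.derived
        in2 = name in panel_rep2.derived
        if in1 and in2:
            m1 = panel_rep1.derived[name]
            m2 = panel_rep2.derived[name]
            out[name] = ReplicateStat(mean=0.5 * (m1 + m2), noise=0.5 * (m1 - m2))
        else:
            which = []
            if not in1:
                which.append("rep1:" + panel_rep1.reasons.get(name, "absent"))
            if not in2:
                which.append("rep2:" + panel_rep2.reasons.get(name, "absent"))
            reasons[name] = ";".join(which)
    return out, reasons


def replicate_concordance(
    quant1: Mapping[str, float], quant2: Mapping[str, float], threshold: float = 0.8
) -> tuple[float, bool]:
    """Spearman rank correlation between two replicate gene quantifications
    over shared genes (average ranks for ties); passes when rho > threshold."""
    shared = sorted(set(quant1) & set(quant2))
    if len(shared) < 3:
        raise ValueError(f"need at least 3 shared genes, got {len(shared)}")
    a = np.array([float(quant1[g]) for g in shared])
    b = np.array([float(quant2[g]) for g in shared])
    rho = float(stats.spearmanr(a, b).statistic)
    return rho, rho > threshold


# -- pair-index summaries ----------------------------------------------------

def pair_index_summary(
    panels: Iterable[MetricsPanel], distal_indices: tuple[int, int] = (3, 10)
) -> pd.DataFrame:
    """Summarize derived metrics by intragenic pair position.

    Emits, per (stratum, metric), rows for pair index 1, pair index 2, and
    the unweighted mean of the log2 metric over pair indices
    ``distal_indices[0]..distal_indices[1]`` (absent indices excluded, the
    number actually averaged reported as ``n``).
    """
    panels = list(panels)
    lo, hi = distal_indices
    rows = []
    strata = sorted({p.stratum for p in panels})
    for stratum in strata:
        sub = [p for p in panels if p.stratum == stratum]
        for metric in METRIC_NAMES:
            for k in (1, 2):
                vals = [p.derived[metric] for p in sub if p.pair_index == k and metric in p.derived]
                if vals:
                    rows.append((stratum, metric, f"pair_{k}", float(np.mean(vals)), len(vals)))
            vals = [
                p.derived[metric]
                for p in sub
                if lo <= p.pair_index <= hi and metric in p.derived
            ]
            if vals:
                rows.append((stratum, metric, f"pairs_{lo}_{hi}", float(np.mean(vals)), len(vals)))
    return pd.DataFrame(rows, columns=["stratum", "metric", "group", "log2_value", "n"])
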