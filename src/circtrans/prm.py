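"""Parallel reaction monitoring (PRM) relative quantification.

Relative protein expression is the ratio of endogenous ("light")
fragment-ion peak areas to those of a spiked heavy-isotope-labeled
synthetic peptide, summed over the shared transition set (ratio of sums,
Skyline's default, which is robust to one weak transition). At least
three transitions per precursor are required — fewer is a refusal, not a
number.
"""

from __future__ import annotations

import logging
import math
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .types import PRMMeasurement

logger = logging.getLogger(__name__)

MIN_TRANSITIONS = 3


class PRMError(ValueError):
    """Quantification refused (too few transitions / zero heavy signal)."""


def compute_prm_ratio(measurement: PRMMeasurement) -> float:
    """Endogenous/heavy ratio over the shared transition set.

    Transitions with a missing (NaN) area in either channel are dropped
    pairwise with a warning. At least three shared transitions must
    remain; the summed heavy area must be positive.
    """
    shared: List[Tuple[str, float, float]] = []
    for frag, light, heavy in measurement.transitions:
        if math.isnan(light) or math.isnan(heavy):
            logger.warning(
                "%s/%s: transition %s present in only one channel; dropped",
                measurement.peptide, measurement.sample_id, frag,
            )
            continue
        shared.append((frag, light, heavy))
    if len(shared) < MIN_TRANSITIONS:
        raise PRMError(
            f"{measurement.peptide}/{measurement.sample_id}: only "
            f"{len(shared)} usable transitions; at least "
            f"{MIN_TRANSITIONS} transitions per precursor are required"
        )
    total_heavy = sum(h for _, _, h in shared)
    if total_heavy == 0:
        raise PRMError(
            f"{measurement.peptide}/{measurement.sample_id}: total heavy "
            f"area is zero; ratio undefined"
        )
    return sum(l for _, l, _ in shared) / total_heavy


def read_prm_table(path) -> List[PRMMeasurement]:
    """Read a Skyline-style transition report CSV.

    Expected columns: peptide, sample, fragment, light_area, heavy_area.
    One PRMMeasurement per (peptide, sample), transitions in file order.
    """
    df = pd.read_csv(path)
    required = {"peptide", "sample", "fragment", "light_area", "heavy_area"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing PRM columns {sorted(missing)}")
    out: List[PRMMeasurement] = []
    for (peptide, sample), grp in df.groupby(["peptide", "sample"], sort=True):
        transitions = tuple(
            (str(row.fragment), float(row.light_area), float(row.heavy_area))
            for row in grp.itertuples()
        )
        out.append(PRMMeasurement(str(peptide), str(sample), transitions))
    return out


def quantify_all(measurements: Sequence[PRMMeasurement]) -> pd.DataFrame:
    """Ratios for every measurement: columns (peptide, sample, ratio)."""
    rows = []
    for m in measurements:
        rows.append(
            {"peptide": m.peptide, "sample": m.sample_id,
             "ratio": compute_prm_ratio(m)}
        )
    return pd.DataFrame(rows, columns=["peptide", "sample", "ratio"])


def compare_conditions(
    ratios: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    welch: bool = True,
) -> pd.DataFrame:
    """Per-peptide fold change (mean_a / mean_b) and two-tailed t-test p.

    ``ratios`` must have columns (peptide, sample, ratio). Welch's
    unequal-variance t-test by default. A group with fewer than two
    samples yields the fold change with p = NaN; a zero denominator mean
    yields fold change NaN and a flag.
    """
    group_a, group_b = list(group_a), list(group_b)
    rows = []
    for peptide, grp in ratios.groupby("peptide", sort=True):
        a = grp.loc[grp["sample"].isin(group_a), "ratio"].to_numpy(float)
        b = grp.loc[grp["sample"].isin(group_b), "ratio"].to_numpy(float)
        mean_a = float(np.mean(a)) if a.size else float("nan")
        mean_b = float(np.mean(b)) if b.size else float("nan")
        degenerate = not np.isfinite(mean_b) or mean_b == 0
        fold = float("nan") if degenerate else mean_a / mean_b
        if a.size >= 2 and b.size >= 2:
            p = float(stats.ttest_ind(a, b, equal_var=not welch).pvalue)
        else:
            p = float("nan")
        rows.append(
            {
                "peptide": peptide,
                "n_a": int(a.size),
                "n_b": int(b.size),
                "mean_a": mean_a,
                "mean_b": mean_b,
                "fold_change": fold,
                "p_value": p,
                "degenerate": bool(degenerate),
            }
        )
    return pd.DataFrame(rows)


def write_prm_report(ratios: pd.DataFrame, path,
                     comparisons: Optional[pd.DataFrame] = None,
                     comparisons_path=None) -> None:
    ratios.to_csv(path, sep="\t", index=False)
    if comparisons is not None and comparisons_path is not None:
        comparisons.to_csv(comparisons_path, sep="\t", index=False)
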