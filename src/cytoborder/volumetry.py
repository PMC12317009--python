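"""Areal volumetry from serial sections and group comparisons.

Volumes follow the Cavalieri principle: the sum of per-section
cross-sectional areas times the slab spacing (section thickness times the
sampling interval), multiplied by a per-brain shrinkage factor (the ratio
of fresh to histologically processed volume).  Inter-hemispheric and
gender differences of whole-brain volume fractions are tested with Monte
Carlo permutation tests and corrected for multiple comparisons across
areas (Benjamini-Hochberg FDR by default, Bonferroni on request).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

VOLUME_COLUMNS = ["brain", "hemisphere", "gender", "area",
                  "volume_mm3", "whole_brain_volume_mm3"]


@dataclass(frozen=True)
class SectionSeries:
    """Measured cross-sectional areas of one area in one hemisphere.

    ``section_areas`` are in mm² per measured section; ``thickness_mm`` is
    the physical section thickness; ``interval`` the sampling interval in
    sections (e.g. every 15th section measured); ``shrinkage`` the
    fresh/processed volume ratio used to correct for processing shrinkage.
    """
    section_areas: tuple[float, ...]
    thickness_mm: float = 0.02
    interval: int = 15
    shrinkage: float = 1.0

    def __post_init__(self) -> None:
        a = np.asarray(self.section_areas, dtype=float)
        if a.size == 0 or np.any(a < 0):
            raise ValueError("section areas must be non-negative and non-empty")
        if self.thickness_mm <= 0:
            raise ValueError("thickness_mm must be positive")
        if self.interval < 1:
            raise ValueError("interval must be >= 1")
        if self.shrinkage < 0:
            raise ValueError("shrinkage must be >= 0")


def cavalieri_volume(series: SectionSeries) -> float:
    """Shrinkage-corrected Cavalieri volume estimate in mm³."""
    return float(np.sum(series.section_areas) * series.thickness_mm
                 * series.interval * series.shrinkage)


def permutation_test(values_a, values_b, n_perm: int = 10_000,
                     seed: int | None = None) -> float:
    """Two-sided Monte Carlo permutation test on the difference of means.

    The p value uses the add-one estimator
    (1 + #{|stat_perm| >= |stat_obs|}) / (n_perm + 1), which never reports
    exactly zero.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_perm < 1000:
        raise ValueError("n_perm must be >= 1000")
    # permuting the sorted pooled sample makes the Monte Carlo p value exactly
    # invariant to swapping equal-sized groups and to common shifts
    pooled = np.sort(np.concatenate([a, b]))
    if np.ptp(pooled) == 0:
        warnings.warn("all pooled values identical; permutation p = 1",
                      RuntimeWarning, stacklevel=2)
        return 1.0
    obs = abs(a.mean() - b.mean())
    rng = np.random.default_rng(seed)
    n, na = pooled.size, a.size
    # vectorised label shuffles: argsort of uniforms gives permutations
    u = rng.random((n_perm, n))
    perm_idx = np.argsort(u, axis=1)
    permuted = pooled[perm_idx]
    stat = np.abs(permuted[:, :na].mean(axis=1) - permuted[:, na:].mean(axis=1))
    return float((1 + np.sum(stat >= obs)) / (n_perm + 1))


def sign_flip_test(differences, n_perm: int = 10_000,
                   seed: int | None = None) -> float:
    """Two-sided paired permutation (sign-flip) test on mean difference."""
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one paired difference")
    if n_perm < 1000:
        raise ValueError("n_perm must be >= 1000")
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; p = 1",
                      RuntimeWarning, stacklevel=2)
        return 1.0
    obs = abs(d.mean())
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, (n_perm, d.size)) * 2 - 1
    stat = np.abs((signs * d).mean(axis=1))
    return float((1 + np.sum(stat >= obs)) / (n_perm + 1))


def fdr_correct(pvalues, q: float = 0.05, method: str = "fdr_bh"):
    """Benjamini-Hochberg step-up correction (or Bonferroni via ``method``).

    Returns (significance mask, adjusted p values); empty input passes
    through as empty arrays.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject, adj, _, _ = multipletests(p, alpha=q, method=method)
    return reject, adj


def compare_volumes(table: pd.DataFrame, factor: str, n_perm: int = 10_000,
                    seed: int | None = None, q: float = 0.05,
                    correction: str = "fdr_bh") -> pd.DataFrame:
    """Per-area permutation tests of whole-brain volume fractions.

    ``factor`` is ``"hemisphere"`` (paired within brain: sign-flip test on
    left-right fraction differences) or ``"gender"`` (unpaired test on
    per-brain mean fractions).  Correction across areas is
    Benjamini-Hochberg by default (``correction="bonferroni"`` for the
    family-wise alternative); both raw and adjusted p values are returned.
    """
    missing = [c for c in VOLUME_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"volume table lacks columns: {missing}")
    if table["whole_brain_volume_mm3"].isna().any():
        raise ValueError("missing whole-brain volume")
    if factor not in ("hemisphere", "gender"):
        raise ValueError("factor must be 'hemisphere' or 'gender'")
    df = table.copy()
    df["fraction"] = df["volume_mm3"] / df["whole_brain_volume_mm3"]
    if ((df["fraction"] < 0) | (df["fraction"] > 1)).any():
        raise ValueError("volume fractions must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    rows = []
    for area, sub in df.groupby("area", sort=True):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if factor == "hemisphere":
            wide = sub.pivot_table(index="brain", columns="hemisphere",
                                   values="fraction", aggfunc="mean")
            if wide.shape[1] != 2 or len(wide.dropna()) < 2:
                raise ValueError(f"area {area!r}: need >= 2 brains with both hemispheres")
            d = wide.dropna().iloc[:, 0] - wide.dropna().iloc[:, 1]
            p = sign_flip_test(d.to_numpy(), n_perm=n_perm, seed=sub_seed)
        else:
            per_brain = sub.groupby(["brain", "gender"], sort=True)["fraction"].mean().reset_index()
            levels = sorted(per_brain["gender"].unique())
            if len(levels) != 2:
                raise ValueError(f"area {area!r}: gender must have exactly 2 levels")
            ga = per_brain.loc[per_brain["gender"] == levels[0], "fraction"].to_numpy()
            gb = per_brain.loc[per_brain["gender"] == levels[1], "fraction"].to_numpy()
            if len(ga) < 2 or len(gb) < 2:
                raise ValueError(f"area {area!r}: need >= 2 brains per gender level")
            p = permutation_test(ga, gb, n_perm=n_perm, seed=sub_seed)
        rows.append({"area": area, "p": p})
    res = pd.DataFrame(rows)
    reject, adj = fdr_correct(res["p"].to_numpy(), q=q, method=correction)
    res["p_adj"] = adj
    res["significant"] = reject
    logger.info("%s comparison: %d of %d areas significant (%s, q=%g)",
                factor, int(reject.sum()), len(res), correction, q)
    return res
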