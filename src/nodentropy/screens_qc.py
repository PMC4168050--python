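"""Differential screens, expression-strength statistics and QC flags.

Screens compare replicate condition groups per gene with a Welch
(unequal-variance) two-sample t-test on linear signals, report the fold
change of group means, and flag genes at an uncorrected p < alpha in the
stated direction — mirroring how compendium-era analyses were run.  An
optional Benjamini–Hochberg mode reports adjusted q-values alongside,
because family-wide screens at a raw alpha are anticonservative.

QC covers two failure modes of compendium assembly:

* cross-contamination — a non-nodule sample carrying bacterial-marker
  signal (markers of the rhizobial symbiont hybridize only in
  nodule-derived material); a condition is flagged when its mean marker
  signal exceeds a robust background of median + z_cut * MAD over the
  non-nodule conditions;
* relaxed specificity — a member of a nodule-specific family showing
  reproducible expression outside nodules; flagged when any non-nodule,
  non-contaminated condition exceeds both an absolute floor above the
  cohort background and a fraction of the gene's own nodule maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .compendium_io import Compendium, MappingError, ValidationError

__all__ = [
    "ScreenResult",
    "MaxSignalStats",
    "two_group_screen",
    "senescence_response",
    "max_signal_stats",
    "flag_relaxed_specificity",
    "detect_contamination",
]


# ---------------------------------------------------------------------------
# two-group screen
# ---------------------------------------------------------------------------


@dataclass
class ScreenResult:
    """Per-gene screen outcome.

    ``frame`` columns: mean_a, mean_b, fold_change (B/A), p_value,
    direction (higher_in_A | higher_in_B | none), flagged; plus q_value
    when BH mode is on.
    """

    frame: pd.DataFrame
    alternative: str
    alpha: float

    @property
    def flagged_genes(self) -> list[str]:
        return list(self.frame.index[self.frame["flagged"]])


def _check_group(compendium: Compendium, group: Sequence[str], name: str) -> list[str]:
    group = list(group)
    if len(group) < 2:
        raise ValidationError(f"group {name} needs >= 2 replicate conditions")
    unknown = [c for c in group if c not in compendium.signals.columns]
    if unknown:
        raise MappingError(f"group {name} names unknown condition(s): {unknown}")
    return group


def two_group_screen(
    compendium: Compendium,
    group_a: Sequence[str],
    group_b: Sequence[str],
    alternative: str = "two_sided",
    alpha: float = 0.05,
    bh: bool = False,
) -> ScreenResult:
    """Welch t-test screen of condition group B against group A.

    ``alternative`` is one of ``two_sided``, ``b_greater`` or
    ``a_greater``.  Flagging requires p < alpha and, for the one-sided
    alternatives, the matching direction of the mean difference.  With
    both groups at zero variance, p is 1 when the means are equal and 0
    otherwise (the degenerate limit of an infinitely confident test).
    """
    group_a = _check_group(compendium, group_a, "A")
    group_b = _check_group(compendium, group_b, "B")
    a = compendium.signals[group_a].to_numpy(dtype=float)
    b = compendium.signals[group_b].to_numpy(dtype=float)

    scipy_alt = {"two_sided": "two-sided", "b_greater": "less", "a_greater": "greater"}
    if alternative not in scipy_alt:
        raise ValueError(f"unknown alternative {alternative!r}")
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # zero-variance rows trip scipy's precision warning; their p-values
        # are replaced by the degenerate-case convention below
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(
            a, b, axis=1, equal_var=False, alternative=scipy_alt[alternative]
        )

    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p = np.where(degenerate & (mean_a == mean_b), 1.0, p)
    p = np.where(degenerate & (mean_a != mean_b), 0.0, p)

    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(mean_a > 0, mean_b / mean_a, np.where(mean_b > 0, np.inf, np.nan))

    direction = np.where(
        mean_b > mean_a, "higher_in_B", np.where(mean_a > mean_b, "higher_in_A", "none")
    )
    flagged = p < alpha
    if alternative == "b_greater":
        flagged &= direction == "higher_in_B"
    elif alternative == "a_greater":
        flagged &= direction == "higher_in_A"
    else:
        flagged &= direction != "none"

    frame = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": fold,
            "p_value": p,
            "direction": direction,
            "flagged": flagged,
        },
        index=compendium.signals.index,
    )
    if bh:
        frame["q_value"] = multipletests(p, method="fdr_bh")[1]
    return ScreenResult(frame, alternative, alpha)


# ---------------------------------------------------------------------------
# senescence response
# ---------------------------------------------------------------------------


@dataclass
class SenescenceResponse:
    """Treated/control ratios per gene and per-family down/up fractions."""

    ratios: pd.DataFrame  # columns: control_mean, treated_mean, ratio, family
    family_summary: pd.DataFrame  # per family: n_defined, frac_down, frac_up


def senescence_response(
    compendium: Compendium,
    control: Sequence[str],
    treated: Sequence[str],
    families: Mapping[str, str] | pd.Series,
) -> SenescenceResponse:
    """Per-gene senescence-induction response, summarized per gene family.

    ``families`` maps gene_id -> family label for the genes of interest;
    genes not mapped are ignored.  Genes with zero control signal have an
    undefined ratio and are excluded from the fractions.
    """
    control = _check_group(compendium, control, "control")
    treated = _check_group(compendium, treated, "treated")
    fam = pd.Series(families, dtype=object)
    genes = [g for g in fam.index if g in compendium.signals.index]
    if not genes:
        raise MappingError("none of the mapped genes exist in the compendium")
    fam = fam[genes]

    c_mean = compendium.signals.loc[genes, control].mean(axis=1)
    t_mean = compendium.signals.loc[genes, treated].mean(axis=1)
    ratio = (t_mean / c_mean.where(c_mean > 0)).astype(float)

    ratios = pd.DataFrame(
        {
            "control_mean": c_mean,
            "treated_mean": t_mean,
            "ratio": ratio,
            "family": fam,
        }
    )
    rows = []
    for family, grp in ratios.groupby("family"):
        defined = grp["ratio"].dropna()
        n = len(defined)
        rows.append(
            {
                "family": family,
                "n_defined": n,
                "frac_down": float((defined < 1).mean()) if n else np.nan,
                "frac_up": float((defined > 1).mean()) if n else np.nan,
            }
        )
    summary = pd.DataFrame(rows).set_index("family")
    return SenescenceResponse(ratios, summary)


# ---------------------------------------------------------------------------
# expression strength
# ---------------------------------------------------------------------------


@dataclass
class MaxSignalStats:
    """Distribution of per-gene maximal signals over all conditions."""

    per_gene_max: pd.Series
    mean: float
    median: float
    #: threshold -> fraction of genes whose max exceeds it
    fraction_above: dict[float, float]


def max_signal_stats(
    compendium: Compendium,
    gene_subset: Sequence[str] | None = None,
    thresholds: Sequence[float] = (5_000, 10_000, 15_000),
) -> MaxSignalStats:
    signals = compendium.signals
    if gene_subset is not None:
        gene_subset = list(gene_subset)
        if not gene_subset:
            raise ValidationError("gene subset is empty")
        missing = [g for g in gene_subset if g not in signals.index]
        if missing:
            raise MappingError(f"unknown gene_id(s): {missing[:5]}")
        signals = signals.loc[gene_subset]
    maxima = signals.max(axis=1)
    fractions = {
        float(t): float((maxima > t).mean()) for t in sorted(thresholds)
    }
    return MaxSignalStats(
        per_gene_max=maxima,
        mean=float(maxima.mean()),
        median=float(maxima.median()),
        fraction_above=fractions,
    )


# ---------------------------------------------------------------------------
# QC: relaxed specificity and contamination
# ---------------------------------------------------------------------------


def flag_relaxed_specificity(
    compendium: Compendium,
    family_genes: Sequence[str],
    target_organ: str = "nodule",
    floor_factor: float = 5.0,
    ratio_cut: float = 0.01,
    exclude_conditions: Sequence[str] = (),
) -> pd.DataFrame:
    """Flag family genes with reproducible expression outside the target organ.

    The cohort background is the median signal of all *non-family* genes
    over non-target conditions.  A family gene is relaxed when, in at
    least one non-target condition (contamination-flagged conditions
    excluded), its signal exceeds
    ``max(floor_factor * background, ratio_cut * its own target-organ
    maximum)``.  Returns a per-gene table with the offending conditions.
    """
    family_genes = list(family_genes)
    if not family_genes:
        raise ValidationError("family gene list is empty")
    missing = [g for g in family_genes if g not in compendium.signals.index]
    if missing:
        raise MappingError(f"unknown family gene(s): {missing[:5]}")

    meta = compendium.conditions
    target_conds = list(meta.index[meta["organ"] == target_organ])
    if not target_conds:
        raise MappingError(f"no conditions with organ {target_organ!r}")
    non_target = [
        c
        for c in meta.index
        if c not in target_conds and c not in set(exclude_conditions)
    ]
    if not non_target:
        raise ValidationError("no usable non-target conditions")

    non_family = compendium.signals.index.difference(family_genes)
    background = float(
        np.median(compendium.signals.loc[non_family, non_target].to_numpy())
    )

    rows = []
    for gene in family_genes:
        target_max = float(compendium.signals.loc[gene, target_conds].max())
        cut = max(floor_factor * background, ratio_cut * target_max)
        outside = compendium.signals.loc[gene, non_target]
        offending = list(outside.index[outside > cut])
        rows.append(
            {
                "gene_id": gene,
                "flagged": bool(offending),
                "threshold": cut,
                "target_max": target_max,
                "offending_conditions": ",".join(offending),
            }
        )
    frame = pd.DataFrame(rows).set_index("gene_id")
    frame.attrs["background"] = background
    return frame


def detect_contamination(
    compendium: Compendium,
    marker_genes: Sequence[str],
    expected_organ: str = "nodule",
    z_cut: float = 5.0,
) -> pd.DataFrame:
    """Flag non-target conditions whose marker signal is implausibly high.

    For every condition outside ``expected_organ`` the marker set is
    summarized by its log2 mean signal (the log of the geometric mean —
    the natural scale for multiplicative hybridization noise) and
    compared against a robust background: the median plus ``z_cut`` times
    the normal-consistent median absolute deviation (1.4826 x MAD, the
    standard robust scale estimate) of those log2 means over the same
    conditions, so ``z_cut`` reads as a robust z-score.
    """
    marker_genes = list(marker_genes)
    if not marker_genes:
        raise ValidationError("marker gene set is empty")
    missing = [g for g in marker_genes if g not in compendium.signals.index]
    if missing:
        raise MappingError(f"unknown marker gene(s): {missing[:5]}")

    meta = compendium.conditions
    non_target = list(meta.index[meta["organ"] != expected_organ])
    if len(non_target) < 3:
        raise ValidationError(
            "need >= 3 non-target conditions to estimate marker background"
        )
    signals = compendium.signals.loc[marker_genes, non_target]
    log_mean = np.log2(signals.clip(lower=1e-12)).mean(axis=0)
    med = float(log_mean.median())
    mad = float(stats.median_abs_deviation(log_mean, scale="normal"))
    threshold = med + z_cut * mad

    frame = pd.DataFrame(
        {
            "marker_geomean": np.exp2(log_mean),
            "log2_marker_mean": log_mean,
            "background_median_log2": med,
            "background_mad_log2": mad,
            "threshold_log2": threshold,
            "flagged": log_mean > threshold,
        }
    )
    frame.index.name = "condition_id"
    return frame
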