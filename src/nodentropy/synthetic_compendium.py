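"""Synthetic expression compendia with fully known planted structure.

The generator emulates the statistical anatomy of a microarray compendium
built around an indeterminate-nodule symbiosis study:

* a panel of whole-organ samples (leaf, petiole, stem, bud, flower, seed,
  pod, root, mycorrhiza) plus a nodule developmental time course in days
  post inoculation (dpi);
* five hand-dissected nodule zone samples (I apical meristem, II infection
  zone, II-III interzone, III fixation zone, IV senescence zone);
* five LCM cell-type samples (M meristem, dIZ/pIZ distal and proximal
  infection zone, IC infected cells, UC uninfected cells);
* a senescence-induction contrast (nitrate-treated nodules);
* a planted nodule-specific gene family activated in three temporal waves,
  with a wave-to-zone spatial correspondence (early waves apical, late
  waves proximal);
* a handful of family genes with deliberately relaxed specificity
  (reproducible root/stem expression), two of which additionally carry a
  planted excess in uninfected over infected cells;
* senescence marker genes (up under induced senescence, zone IV biased)
  and bacterial marker genes (present only in nodule-derived material);
* one cross-contaminated sample: a mycorrhiza column mixed with a
  configurable proportion of a nodule column.

Signals live on the linear hybridization scale: per-gene baselines are
log-normal around a background of ~9, peaks reach the configured ceiling
(~33,500), and every cell carries mean-preserving multiplicative
log-normal noise.  Everything is a deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .compendium_io import Compendium, LCM_CLASSES, ZONE_CLASSES

__all__ = ["SyntheticConfig", "SyntheticTruth", "ConfigError", "simulate_compendium"]


class ConfigError(ValueError):
    """Invalid synthetic-compendium configuration."""


#: logistic activation midpoint / scale (in dpi) per temporal wave.  The
#: steep first wave turns on between 3 and 4 dpi, the second between 4 and
#: 6 dpi, the third between 6 and 10 dpi; nothing is active at <= 3 dpi.
WAVE_LOGISTIC: dict[int, tuple[float, float]] = {
    1: (3.5, 0.2),
    2: (5.5, 0.6),
    3: (9.0, 0.8),
}

#: relative expression of a family gene across nodule zones I..IV by wave.
WAVE_ZONE_WEIGHTS: dict[int, tuple[float, ...]] = {
    1: (1.0, 0.8, 0.45, 0.3, 0.06),
    2: (0.3, 1.0, 0.9, 0.6, 0.12),
    3: (0.05, 0.3, 0.9, 1.0, 0.2),
}

#: relative expression across LCM samples (M, dIZ, pIZ, IC, UC) by wave.
#: The meristem is rhizobium-free, hence silent; the UC weight is the small
#: cross-contamination/amplification floor seen in LCM material.
WAVE_LCM_WEIGHTS: dict[int, tuple[float, ...]] = {
    1: (0.02, 1.0, 0.9, 0.8, 0.04),
    2: (0.02, 0.6, 1.0, 0.9, 0.04),
    3: (0.02, 0.1, 0.6, 1.0, 0.04),
}

ZONE_IV_MARKER_WEIGHTS = (0.02, 0.05, 0.1, 0.2, 1.0)
BACTERIAL_ZONE_WEIGHTS = (0.05, 0.8, 1.0, 1.0, 0.6)
BACTERIAL_LCM_WEIGHTS = (0.02, 0.7, 0.9, 1.0, 0.05)


def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def wave_activation(timepoints_dpi: Sequence[float], wave: int) -> np.ndarray:
    """Fractional activation of a wave at each dpi (0 at <= 3 dpi)."""
    mid, scale = WAVE_LOGISTIC[wave]
    t = np.asarray(timepoints_dpi, dtype=float)
    act = np.asarray(_logistic((t - mid) / scale))
    act[t <= 3.0] = 0.0
    return act


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the generator; defaults are the study conditions."""

    n_genes: int = 500
    n_family: int = 60
    n_relaxed: int = 5
    n_senescence_markers: int = 8
    n_bacterial_markers: int = 10
    #: fraction of non-family genes with organ-specific (non-nodule) expression
    specific_fraction: float = 0.06
    #: whole-organ panel: organ -> replicate count
    tissue_panel: Mapping[str, int] = field(
        default_factory=lambda: {
            "leaf": 3,
            "petiole": 3,
            "stem": 3,
            "bud": 3,
            "flower": 3,
            "pod": 3,
            "root": 3,
            "mycorrhiza": 3,
        }
    )
    seed_dap_stages: tuple[float, ...] = (10, 12, 16, 20, 24, 36)
    nodule_timepoints: tuple[float, ...] = (0, 3, 4, 6, 10, 14, 28)
    n_timecourse_replicates: int = 3
    zone_samples: bool = True
    n_zone_replicates: int = 3
    lcm_samples: bool = True
    n_lcm_replicates: int = 3
    senescence_contrast: bool = True
    n_senescence_replicates: int = 3
    wave_fractions: tuple[float, float, float] = (0.2, 0.5, 0.3)
    declining_fraction: float = 0.3
    decline_factor: float = 0.25
    background_mean: float = 9.0
    #: log-scale sd of per-gene baseline (probe-affinity) spread
    background_sigma: float = 0.8
    peak_signal_range: tuple[float, float] = (5_000.0, 33_500.0)
    noise_cv: float = 0.2
    senescence_down_factor: float = 0.2
    senescence_up_factor: float = 5.0
    #: UC/IC fold excess planted on the first relaxed genes
    uc_folds: tuple[float, ...] = (9.6, 3.2)
    #: relaxed genes' root/stem level as a fraction of their nodule peak
    relaxed_level_range: tuple[float, float] = (0.25, 0.5)
    #: (target condition, donor condition, mixing proportion in (0, 1))
    contamination: tuple[str, str, float] | None = (
        "mycorrhiza_r3",
        "nodule_14dpi_r1",
        0.2,
    )
    seed: int = 0
    #: internal: suppress all planted structure (see :func:`null_config`)
    _null: bool = False

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_family <= 0:
            raise ConfigError("n_genes and n_family must be positive")
        n_special = (
            self.n_family
            + self.n_relaxed
            + self.n_senescence_markers
            + self.n_bacterial_markers
        )
        if self.n_family + self.n_relaxed > self.n_genes:
            raise ConfigError("n_family + n_relaxed exceeds n_genes")
        if n_special > self.n_genes:
            raise ConfigError("special gene classes exceed n_genes")
        if abs(sum(self.wave_fractions) - 1.0) > 1e-9:
            raise ConfigError("wave_fractions must sum to 1")
        if self.contamination is not None:
            p = self.contamination[2]
            if not (0.0 < p < 1.0):
                raise ConfigError("contamination mixing proportion must be in (0,1)")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be non-negative")
        lo, hi = self.peak_signal_range
        if not (0 < lo <= hi):
            raise ConfigError("peak_signal_range must be positive and ordered")

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


def null_config(n_genes: int = 400, seed: int = 0, **overrides) -> SyntheticConfig:
    """A structure-free configuration: pure noise around gene baselines.

    Family size 1 is a formality (the single 'family' gene is generated as
    an ordinary broad gene); no relaxed genes, markers or contamination are
    planted, so every screen runs under its null hypothesis.
    """
    return SyntheticConfig(
        n_genes=n_genes,
        n_family=1,
        n_relaxed=0,
        n_senescence_markers=0,
        n_bacterial_markers=0,
        specific_fraction=0.0,
        contamination=None,
        seed=seed,
        _null=True,
        **overrides,
    )


@dataclass
class SyntheticTruth:
    """Planted labels for recovery testing.

    ``genes``: per gene — family, wave ('1'|'2'|'3'|'none'), relaxed,
    senescence_marker, bacterial_marker, uc_specific (planted UC/IC fold, 0
    when absent), specific_organ (non-family organ-specific genes).
    ``conditions``: per condition — contaminated flag and true mixing
    proportion.
    """

    genes: pd.DataFrame
    conditions: pd.DataFrame

    @property
    def family_genes(self) -> list[str]:
        return list(self.genes.index[self.genes["family"]])

    @property
    def relaxed_genes(self) -> list[str]:
        return list(self.genes.index[self.genes["relaxed"]])

    @property
    def contaminated_conditions(self) -> list[str]:
        return list(self.conditions.index[self.conditions["contaminated"]])


# ---------------------------------------------------------------------------
# condition table
# ---------------------------------------------------------------------------


def _build_conditions(config: SyntheticConfig) -> pd.DataFrame:
    rows: list[dict] = []

    def add(cid, organ, treatment="none", timepoint=np.nan, unit="",
            sample_class="whole_organ", group=""):
        rows.append(
            dict(
                condition_id=cid,
                organ=organ,
                treatment=treatment,
                timepoint=timepoint,
                timepoint_unit=unit,
                sample_class=sample_class,
                replicate_group=group or cid,
            )
        )

    for organ, n_rep in config.tissue_panel.items():
        for r in range(1, n_rep + 1):
            add(f"{organ}_r{r}", organ, group=organ)

    for dap in config.seed_dap_stages:
        add(f"seed_{dap:g}dap", "seed", timepoint=dap, unit="dap", group="seed_dev")

    for dpi in config.nodule_timepoints:
        # 0 and 3 dpi material is root tissue (uninoculated control and
        # nodule primordia still embedded in the root)
        organ = "root" if dpi <= 3 else "nodule"
        for r in range(1, config.n_timecourse_replicates + 1):
            add(
                f"nodule_{dpi:g}dpi_r{r}",
                organ,
                timepoint=dpi,
                unit="dpi",
                group=f"nodule_{dpi:g}dpi",
            )

    if config.zone_samples:
        for zone in ZONE_CLASSES:
            for r in range(1, config.n_zone_replicates + 1):
                add(
                    f"nodule_{zone}_r{r}",
                    "nodule",
                    timepoint=28,
                    unit="dpi",
                    sample_class=zone,
                    group=f"nodule_{zone}",
                )

    if config.lcm_samples:
        for cls in LCM_CLASSES:
            for r in range(1, config.n_lcm_replicates + 1):
                add(
                    f"nodule_{cls}_r{r}",
                    "nodule",
                    sample_class=cls,
                    group=f"nodule_{cls}",
                )

    if config.senescence_contrast:
        for r in range(1, config.n_senescence_replicates + 1):
            add(
                f"nodule_16dpi_nitrate_r{r}",
                "nodule",
                treatment="nitrate",
                timepoint=16,
                unit="dpi",
                group="nodule_senescence",
            )

    meta = pd.DataFrame(rows).set_index("condition_id")
    return meta


# ---------------------------------------------------------------------------
# gene parameter assignment
# ---------------------------------------------------------------------------


def _assign_genes(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_genes
    null = getattr(config, "_null", False)
    n_family = 0 if null else config.n_family
    n_relaxed = 0 if null else config.n_relaxed

    ids: list[str] = []
    ids += [f"NCR{i:04d}" for i in range(1, n_family + n_relaxed + 1)]
    ids += [f"SEN{i:02d}" for i in range(1, config.n_senescence_markers + 1)]
    ids += [f"BAC{i:02d}" for i in range(1, config.n_bacterial_markers + 1)]
    n_other = n - len(ids)
    ids += [f"GENE{i:04d}" for i in range(1, n_other + 1)]

    genes = pd.DataFrame(index=pd.Index(ids, name="gene_id"))
    genes["family"] = [g.startswith("NCR") for g in ids]
    relaxed = np.zeros(n, dtype=bool)
    relaxed[n_family : n_family + n_relaxed] = True
    genes["relaxed"] = relaxed
    genes["senescence_marker"] = [g.startswith("SEN") for g in ids]
    genes["bacterial_marker"] = [g.startswith("BAC") for g in ids]

    # waves for family genes
    waves = np.array(["none"] * n, dtype=object)
    fam_idx = np.flatnonzero(genes["family"].to_numpy())
    if len(fam_idx):
        labels = rng.choice(
            [1, 2, 3], size=len(fam_idx), p=np.asarray(config.wave_fractions)
        )
        waves[fam_idx] = [str(w) for w in labels]
    genes["wave"] = waves

    genes["declining"] = False
    if len(fam_idx):
        early = fam_idx[np.isin(waves[fam_idx], ["1", "2"])]
        genes.loc[genes.index[early], "declining"] = (
            rng.random(len(early)) < config.declining_fraction
        )

    # per-gene baselines (probe affinity spread); bacterial probe-sets on a
    # plant array cross-hybridize uniformly low, so their baseline spread
    # is much tighter than the plant probes'
    baseline = config.background_mean * np.exp(
        rng.normal(0.0, config.background_sigma, size=n)
    )
    bac_mask = genes["bacterial_marker"].to_numpy()
    baseline[bac_mask] = config.background_mean * np.exp(
        rng.normal(0.0, 0.3, size=int(bac_mask.sum()))
    )
    genes["baseline"] = baseline

    # family peaks, log-uniform over the configured range
    lo, hi = config.peak_signal_range
    peaks = np.zeros(n)
    peaks[fam_idx] = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(fam_idx)))
    genes["peak"] = peaks

    # planted UC/IC folds go on the relaxed genes first, then strict
    # family genes; carriers get modest peaks (their uninfected-cell excess
    # must stay below the signal ceiling) and near-parity outside levels
    uc_fold = np.zeros(n)
    rel_idx = np.flatnonzero(relaxed)
    carriers = list(rel_idx) + [i for i in fam_idx if i not in rel_idx]
    folds = () if null else config.uc_folds
    carrier_idx = []
    for fold, idx in zip(folds, carriers):
        uc_fold[idx] = fold
        carrier_idx.append(idx)
    genes["uc_fold"] = uc_fold
    if carrier_idx:
        peaks[carrier_idx] = np.exp(
            rng.uniform(np.log(1500.0), np.log(3500.0), size=len(carrier_idx))
        )
        genes["peak"] = peaks

    # relaxed genes: root/stem level as a fraction of their nodule peak;
    # UC carriers sit near parity with their nodule level
    r_lo, r_hi = config.relaxed_level_range
    relaxed_level = np.zeros(n)
    relaxed_level[rel_idx] = peaks[rel_idx] * rng.uniform(r_lo, r_hi, size=len(rel_idx))
    for idx in carrier_idx:
        if relaxed[idx]:
            relaxed_level[idx] = peaks[idx] * rng.uniform(0.6, 0.95)
    genes["relaxed_level"] = relaxed_level

    # marker base levels
    base_level = np.zeros(n)
    sen_idx = np.flatnonzero(genes["senescence_marker"].to_numpy())
    bac_idx = np.flatnonzero(genes["bacterial_marker"].to_numpy())
    base_level[sen_idx] = np.exp(rng.normal(np.log(300.0), 0.5, size=len(sen_idx)))
    base_level[bac_idx] = np.exp(rng.normal(np.log(3000.0), 0.5, size=len(bac_idx)))
    genes["marker_level"] = base_level

    # ordinary genes: overall level and per-organ modulation; a minority
    # are organ-specific outside the nodule
    other_idx = np.flatnonzero(
        ~(
            genes["family"]
            | genes["senescence_marker"]
            | genes["bacterial_marker"]
        ).to_numpy()
    )
    level = np.zeros(n)
    level[other_idx] = np.exp(rng.normal(np.log(100.0), 1.2, size=len(other_idx)))
    genes["broad_level"] = level

    specific_organ = np.array([""] * n, dtype=object)
    specific_level = np.zeros(n)
    n_specific = int(round(config.specific_fraction * len(other_idx)))
    if n_specific:
        chosen = rng.choice(other_idx, size=n_specific, replace=False)
        organ_pool = ["seed", "flower", "pod", "root", "leaf"]
        specific_organ[chosen] = rng.choice(organ_pool, size=n_specific)
        specific_level[chosen] = np.exp(
            rng.uniform(np.log(800.0), np.log(4000.0), size=n_specific)
        )
    genes["specific_organ"] = specific_organ
    genes["specific_level"] = specific_level

    return genes


# ---------------------------------------------------------------------------
# mean-signal construction
# ---------------------------------------------------------------------------


def _organ_multipliers(
    genes: pd.DataFrame, organs: Sequence[str], rng: np.random.Generator
) -> pd.DataFrame:
    """Mild per-(gene, organ) modulation for broadly expressed genes."""
    mult = np.exp(rng.normal(0.0, 0.5, size=(len(genes), len(organs))))
    return pd.DataFrame(mult, index=genes.index, columns=list(organs))


def _mean_matrix(
    config: SyntheticConfig,
    genes: pd.DataFrame,
    meta: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    organs = sorted(set(meta["organ"]))
    mult = _organ_multipliers(genes, organs, rng)

    baseline = genes["baseline"].to_numpy()
    peak = genes["peak"].to_numpy()
    family = genes["family"].to_numpy()
    sen = genes["senescence_marker"].to_numpy()
    bac = genes["bacterial_marker"].to_numpy()
    broad = ~(family | sen | bac)
    wave = genes["wave"].to_numpy()
    declining = genes["declining"].to_numpy()
    leak = 0.02  # basal leak of non-family organ-specific genes

    zone_pos = {z: i for i, z in enumerate(ZONE_CLASSES)}
    lcm_pos = {c: i for i, c in enumerate(LCM_CLASSES)}

    cols: dict[str, np.ndarray] = {}
    for cid, row in meta.iterrows():
        organ = row["organ"]
        cls = row["sample_class"]
        treatment = row["treatment"]
        dpi = row["timepoint"] if row["timepoint_unit"] == "dpi" else np.nan

        signal = baseline.copy()

        # broadly expressed genes: level x organ modulation everywhere
        signal[broad] = (
            baseline[broad]
            + genes["broad_level"].to_numpy()[broad] * mult.loc[broad, organ].to_numpy()
        )
        # organ-specific non-family genes override the broad profile
        spec = (genes["specific_organ"] == organ).to_numpy()
        spec_any = (genes["specific_organ"] != "").to_numpy()
        signal[spec_any] = baseline[spec_any] + leak * genes["specific_level"].to_numpy()[spec_any]
        signal[spec] = baseline[spec] + genes["specific_level"].to_numpy()[spec]

        # family genes
        if treatment == "nitrate":
            sel = family
            signal[sel] = baseline[sel] + config.senescence_down_factor * peak[sel]
        elif cls == "whole_organ" and not np.isnan(dpi) and organ in ("nodule", "root"):
            # inoculation time course (0/3 dpi are root-stage samples)
            for w in (1, 2, 3):
                sel = family & (wave == str(w))
                act = float(wave_activation([dpi], w)[0])
                if dpi >= 28:
                    act = act * np.where(declining[sel], config.decline_factor, 1.0)
                signal[sel] = baseline[sel] + peak[sel] * act
        elif cls in zone_pos:
            for w in (1, 2, 3):
                sel = family & (wave == str(w))
                signal[sel] = (
                    baseline[sel] + peak[sel] * WAVE_ZONE_WEIGHTS[w][zone_pos[cls]]
                )
        elif cls in lcm_pos:
            for w in (1, 2, 3):
                sel = family & (wave == str(w))
                signal[sel] = (
                    baseline[sel] + peak[sel] * WAVE_LCM_WEIGHTS[w][lcm_pos[cls]]
                )
        else:
            # non-nodule organ: family genes sit at background, except the
            # relaxed ones in root/stem material
            if organ in ("root", "stem"):
                rel = genes["relaxed"].to_numpy()
                signal[rel] = baseline[rel] + genes["relaxed_level"].to_numpy()[rel]

        # relaxed genes are root-expressed also in the 0/3 dpi root-stage
        # time-course samples handled above
        if cls == "whole_organ" and not np.isnan(dpi) and organ == "root":
            rel = genes["relaxed"].to_numpy()
            signal[rel] = baseline[rel] + genes["relaxed_level"].to_numpy()[rel]

        # UC-excess carriers: pin the UC column so that the planted
        # mean-level fold UC/IC is exact
        if cls == "lcm_UC":
            carriers = (genes["uc_fold"] > 0).to_numpy()
            if carriers.any():
                ic = np.zeros(len(genes))
                for w in (1, 2, 3):
                    sel = family & (wave == str(w))
                    ic[sel] = baseline[sel] + peak[sel] * WAVE_LCM_WEIGHTS[w][lcm_pos["lcm_IC"]]
                signal[carriers] = genes["uc_fold"].to_numpy()[carriers] * ic[carriers]

        # senescence markers
        if sen.any():
            if treatment == "nitrate":
                signal[sen] = baseline[sen] + (
                    config.senescence_up_factor * 0.15 * genes["marker_level"].to_numpy()[sen]
                )
            elif cls in zone_pos:
                signal[sen] = baseline[sen] + (
                    genes["marker_level"].to_numpy()[sen]
                    * ZONE_IV_MARKER_WEIGHTS[zone_pos[cls]]
                )
            elif organ == "nodule":
                signal[sen] = baseline[sen] + 0.15 * genes["marker_level"].to_numpy()[sen]
            else:
                signal[sen] = baseline[sen]

        # bacterial markers: only nodule-derived material carries signal
        if bac.any():
            lvl = genes["marker_level"].to_numpy()[bac]
            if cls in zone_pos:
                signal[bac] = baseline[bac] + lvl * BACTERIAL_ZONE_WEIGHTS[zone_pos[cls]]
            elif cls in lcm_pos:
                signal[bac] = baseline[bac] + lvl * BACTERIAL_LCM_WEIGHTS[lcm_pos[cls]]
            elif treatment == "nitrate":
                signal[bac] = baseline[bac] + 0.5 * lvl
            elif organ == "nodule" and not np.isnan(dpi):
                inf = float(_logistic((dpi - 5.0) / 1.2)) if dpi > 3 else 0.0
                signal[bac] = baseline[bac] + lvl * inf
            else:
                signal[bac] = baseline[bac]

        cols[cid] = signal

    return pd.DataFrame(cols, index=genes.index)


# ---------------------------------------------------------------------------
# public entry point
# ---------------------------------------------------------------------------


def simulate_compendium(config: SyntheticConfig) -> tuple[Compendium, SyntheticTruth]:
    """Generate a compendium and its planted ground truth.

    Deterministic given ``config.seed``; same config and seed give
    bit-identical matrices.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    meta = _build_conditions(config)
    genes = _assign_genes(config, rng)
    means = _mean_matrix(config, genes, meta, rng)

    # mean-preserving multiplicative log-normal noise
    if config.noise_cv > 0:
        s = np.sqrt(np.log1p(config.noise_cv**2))
        noise = np.exp(rng.normal(-0.5 * s * s, s, size=means.shape))
    else:
        noise = np.ones(means.shape)
    signals = means * noise

    contaminated = pd.Series(False, index=meta.index)
    mixing = pd.Series(0.0, index=meta.index)
    if config.contamination is not None:
        target, donor, p = config.contamination
        for cid, what in ((target, "target"), (donor, "donor")):
            if cid not in signals.columns:
                raise ConfigError(
                    f"contamination {what} condition {cid!r} does not exist"
                )
        signals[target] = (1.0 - p) * signals[target] + p * signals[donor]
        contaminated[target] = True
        mixing[target] = p

    null = getattr(config, "_null", False)
    truth_genes = genes[
        ["family", "wave", "relaxed", "senescence_marker", "bacterial_marker",
         "uc_fold", "specific_organ", "declining"]
    ].copy()
    if null:
        truth_genes["family"] = False
        truth_genes["wave"] = "none"
    truth_genes["uc_specific"] = truth_genes["uc_fold"] > 0
    truth_cond = pd.DataFrame(
        {"contaminated": contaminated, "mixing": mixing}, index=meta.index
    )
    truth_cond.index.name = "condition_id"

    compendium = Compendium(signals, meta)
    truth = SyntheticTruth(truth_genes, truth_cond)
    return compendium, truth


def truth_to_table(truth: SyntheticTruth) -> pd.DataFrame:
    """Flatten truth labels into one exportable per-gene table."""
    table = truth.genes.copy()
    table.index.name = "gene_id"
    return table
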