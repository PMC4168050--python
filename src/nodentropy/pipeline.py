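"""End-to-end orchestration: simulate -> entropy -> waves/zones -> screens -> QC.

``run_pipeline`` executes the enabled stages in dependency order on either
a synthetic compendium (generated in-process from a
:class:`~nodentropy.synthetic_compendium.SyntheticConfig`) or a real one
loaded from TSV files, writes every stage's tables to the output
directory, and returns a machine-readable summary that is a pure function
of (inputs, configuration, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import compendium_io as cio
from . import screens_qc, spatiotemporal, tissue_entropy
from .compendium_io import Compendium, GeneAnnotation, ValidationError
from .synthetic_compendium import (
    SyntheticConfig,
    SyntheticTruth,
    simulate_compendium,
    truth_to_table,
)

log = logging.getLogger("nodentropy")

ALL_STAGES = ("entropy", "waves", "zones", "screens", "qc")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``synthetic`` or the (matrix, metadata) path pair must
    be supplied.  Threshold defaults mirror the module-level defaults so a
    bare run reproduces the documented behaviour.
    """

    synthetic: SyntheticConfig | None = None
    matrix_path: str | None = None
    metadata_path: str | None = None
    annotation_path: str | None = None
    tissue_map_path: str | None = None
    stages: Sequence[str] = ALL_STAGES
    k: int | None = None
    k_fraction: float = 0.2
    alpha: float = 0.05
    bh: bool = False
    activation_fraction: float = 0.5
    decline_fraction: float = 0.5
    floor_factor: float = 5.0
    ratio_cut: float = 0.01
    z_cut: float = 5.0
    outdir: str = "nodentropy_run"
    seed: int | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        real = self.matrix_path is not None and self.metadata_path is not None
        if bool(self.synthetic) == real:
            raise ValidationError(
                "supply exactly one of a synthetic config or matrix+metadata paths"
            )
        unknown = sorted(set(self.stages) - set(ALL_STAGES))
        if unknown:
            raise ValidationError(f"unknown stage(s): {unknown}")
        for name, value, lo, hi in (
            ("alpha", self.alpha, 0.0, 1.0),
            ("activation_fraction", self.activation_fraction, 0.0, 1.0),
            ("decline_fraction", self.decline_fraction, 0.0, 1.0),
            ("ratio_cut", self.ratio_cut, 0.0, 1.0),
            ("k_fraction", self.k_fraction, 0.0, 1.0),
        ):
            if not (lo < value <= hi):
                raise ValidationError(f"{name}={value} outside ({lo}, {hi}]")
        if self.floor_factor < 0 or self.z_cut < 0:
            raise ValidationError("floor_factor and z_cut must be non-negative")


def load_run_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration (versioned schema, v1)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    version = raw.pop("schema_version", 1)
    if version != 1:
        raise ValidationError(f"unsupported config schema_version {version}")
    synth = raw.pop("synthetic", None)
    cfg = RunConfig(**raw)
    if synth is not None:
        cfg.synthetic = SyntheticConfig(**synth)
    return cfg


# ---------------------------------------------------------------------------


def _family_labels(
    truth: SyntheticTruth | None, annotation: GeneAnnotation | None
) -> pd.DataFrame | None:
    """Per-gene family/marker membership from truth or annotations."""
    if truth is not None:
        return pd.DataFrame(
            {
                "family": truth.genes["family"],
                "senescence_marker": truth.genes["senescence_marker"],
                "bacterial_marker": truth.genes["bacterial_marker"],
            }
        )
    if annotation is not None:
        table = annotation.table
        return pd.DataFrame(
            {
                "family": table["family"] == "NCR",
                "senescence_marker": table["family"] == "senescence_marker",
                "bacterial_marker": table["family"] == "bacterial_marker",
            }
        )
    return None


def _conditions_by_class(compendium: Compendium, sample_class: str) -> list[str]:
    meta = compendium.conditions
    return list(meta.index[meta["sample_class"] == sample_class])


def _round(x: float | None, digits: int = 6) -> float | None:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return None
    return round(float(x), digits)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the enabled stages and return the JSON-ready summary."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    truth: SyntheticTruth | None = None
    annotation: GeneAnnotation | None = None
    if config.synthetic is not None:
        synth = config.synthetic
        if config.seed is not None:
            synth = synth.with_seed(config.seed)
        log.info("simulating compendium (seed=%d)", synth.seed)
        compendium, truth = simulate_compendium(synth)
        cio.write_compendium(
            compendium, outdir / "matrix.tsv", outdir / "metadata.tsv"
        )
        cio.write_table(truth_to_table(truth), outdir / "truth.tsv", index=True)
    else:
        compendium = cio.read_compendium(config.matrix_path, config.metadata_path)
        if config.annotation_path:
            annotation = cio.read_annotations(config.annotation_path)

    labels = _family_labels(truth, annotation)
    family_genes = (
        list(labels.index[labels["family"]]) if labels is not None else []
    )

    summary: dict[str, Any] = {
        "schema_version": 1,
        "n_genes": compendium.n_genes,
        "n_conditions": compendium.n_conditions,
        "thresholds": {
            "alpha": config.alpha,
            "activation_fraction": config.activation_fraction,
            "decline_fraction": config.decline_fraction,
            "floor_factor": config.floor_factor,
            "ratio_cut": config.ratio_cut,
            "z_cut": config.z_cut,
        },
        "stages": {},
    }

    qc_flags: list[str] = []
    stages = list(config.stages)

    if "qc" in stages:
        summary["stages"]["qc"] = _stage_qc(
            config, compendium, labels, family_genes, outdir, qc_flags
        )
    if "entropy" in stages:
        summary["stages"]["entropy"] = _stage_entropy(
            config, compendium, family_genes, outdir
        )
    if "waves" in stages:
        summary["stages"]["waves"] = _stage_waves(
            config, compendium, truth, family_genes, outdir
        )
    if "zones" in stages:
        summary["stages"]["zones"] = _stage_zones(
            config, compendium, family_genes, outdir
        )
    if "screens" in stages:
        summary["stages"]["screens"] = _stage_screens(
            config, compendium, labels, family_genes, outdir
        )

    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_entropy(
    config: RunConfig,
    compendium: Compendium,
    family_genes: list[str],
    outdir: Path,
) -> dict[str, Any]:
    if config.tissue_map_path:
        tmap = tissue_entropy.load_tissue_map(config.tissue_map_path)
    else:
        tmap = tissue_entropy.default_tissue_map(compendium)
    log.info(
        "tissue map: %s",
        {name: len(conds) for name, conds in tmap.tissues},
    )
    profile = tissue_entropy.aggregate_tissues(compendium, tmap)
    relative = tissue_entropy.relative_expression(profile)
    table = tissue_entropy.shannon_entropy(relative)
    out = table.frame.copy()
    out.index.name = "gene_id"
    cio.write_table(out, outdir / "entropy.tsv", index=True)

    n_defined = int(table.defined.sum())
    k = config.k if config.k is not None else int(round(config.k_fraction * n_defined))
    k = min(k, n_defined)
    selected = tissue_entropy.select_most_specific(table, k)
    result: dict[str, Any] = {
        "n_tissues": tmap.n,
        "n_defined": n_defined,
        "k": k,
        "max_entropy": _round(float(np.log2(tmap.n))),
    }
    if family_genes:
        in_sel = len(set(family_genes) & set(selected))
        fam_ranks = table.frame.loc[family_genes, "rank"].dropna()
        # Haldane-corrected odds ratio of family membership in the
        # low-entropy selection
        a = in_sel + 0.5
        b = len(family_genes) - in_sel + 0.5
        c = k - in_sel + 0.5
        d = (n_defined - k) - (len(family_genes) - in_sel) + 0.5
        result.update(
            {
                "family_total": len(family_genes),
                "family_in_selected": in_sel,
                "family_recovery": _round(in_sel / len(family_genes)),
                "median_family_rank": _round(float(fam_ranks.median())),
                "low_entropy_odds_ratio": _round((a / b) / (c / d), 3),
            }
        )
    return result


def _stage_waves(
    config: RunConfig,
    compendium: Compendium,
    truth: SyntheticTruth | None,
    family_genes: list[str],
    outdir: Path,
) -> dict[str, Any]:
    ratios = spatiotemporal.temporal_ratios(compendium)
    background = float(
        config.synthetic.background_mean if config.synthetic else 9.0
    )
    waves = spatiotemporal.assign_waves(
        ratios,
        activation_fraction=config.activation_fraction,
        decline_fraction=config.decline_fraction,
        background=background,
        floor_factor=config.floor_factor,
    )
    out = waves.frame.copy()
    out.index.name = "gene_id"
    cio.write_table(out, outdir / "waves.tsv", index=True)
    ratio_out = ratios.ratios.copy()
    ratio_out.columns = [f"ratio_{c:g}dpi" for c in ratio_out.columns]
    ratio_out.index.name = "gene_id"
    cio.write_table(ratio_out, outdir / "temporal_ratios.tsv", index=True)

    subset = family_genes or list(compendium.gene_ids)
    counts = waves.frame.loc[subset, "wave"].value_counts().to_dict()
    result: dict[str, Any] = {
        "family_wave_counts": {str(k): int(v) for k, v in sorted(counts.items())}
    }
    if truth is not None and family_genes:
        planted = truth.genes.loc[family_genes, "wave"]
        called = waves.frame.loc[family_genes, "wave"]
        result["wave_recovery"] = _round(float((planted == called).mean()))
    corr = spatiotemporal.timepoint_correlation(
        compendium, gene_subset=family_genes or None
    )
    corr_out = corr.copy()
    corr_out.index = [f"{c:g}dpi" for c in corr_out.index]
    corr_out.columns = [f"{c:g}dpi" for c in corr_out.columns]
    corr_out.index.name = "dpi"
    cio.write_table(corr_out, outdir / "timepoint_correlation.tsv", index=True)
    return result


def _stage_zones(
    config: RunConfig,
    compendium: Compendium,
    family_genes: list[str],
    outdir: Path,
) -> dict[str, Any]:
    profile = spatiotemporal.zone_relative_profile(compendium)
    out = profile.values.copy()
    out.index.name = "gene_id"
    cio.write_table(out, outdir / "zone_profiles.tsv", index=True)

    result: dict[str, Any] = {"n_defined": int(profile.defined.sum())}
    subset = [g for g in family_genes if profile.defined.get(g, False)]
    if len(subset) >= 2:
        dendro = spatiotemporal.hierarchical_cluster(
            profile.values.loc[subset], distance="pearson"
        )
        (outdir / "zone_dendrogram.nwk").write_text(
            dendro.to_newick() + "\n", encoding="utf-8"
        )
        result["n_clustered_family_genes"] = len(subset)
    return result


def _stage_screens(
    config: RunConfig,
    compendium: Compendium,
    labels: pd.DataFrame | None,
    family_genes: list[str],
    outdir: Path,
) -> dict[str, Any]:
    meta = compendium.conditions
    result: dict[str, Any] = {}

    zone3 = _conditions_by_class(compendium, "zone_III")
    zone4 = _conditions_by_class(compendium, "zone_IV")
    if len(zone3) >= 2 and len(zone4) >= 2:
        screen = screens_qc.two_group_screen(
            compendium, zone3, zone4, alternative="b_greater",
            alpha=config.alpha, bh=config.bh,
        )
        out = screen.frame.copy()
        out.index.name = "gene_id"
        cio.write_table(out, outdir / "screen_zone_III_vs_IV.tsv", index=True)
        flagged = screen.flagged_genes
        fam_flagged = [g for g in flagged if g in set(family_genes)]
        result["zone_III_vs_IV"] = {
            "n_flagged_higher_in_IV": len(flagged),
            "n_family_flagged_higher_in_IV": len(fam_flagged),
        }

    ic = _conditions_by_class(compendium, "lcm_IC")
    uc = _conditions_by_class(compendium, "lcm_UC")
    if len(ic) >= 2 and len(uc) >= 2:
        screen = screens_qc.two_group_screen(
            compendium, ic, uc, alternative="b_greater",
            alpha=config.alpha, bh=config.bh,
        )
        out = screen.frame.copy()
        out.index.name = "gene_id"
        cio.write_table(out, outdir / "screen_UC_vs_IC.tsv", index=True)
        frame = screen.frame
        if family_genes:
            frame = frame.loc[[g for g in family_genes if g in frame.index]]
        flagged = frame[frame["flagged"]]
        top = flagged["fold_change"].idxmax() if len(flagged) else None
        result["uc_vs_ic"] = {
            "n_flagged_higher_in_UC": int(frame["flagged"].sum()),
            "top_hit": top,
            "top_fold": _round(float(flagged.loc[top, "fold_change"]), 3)
            if top is not None
            else None,
        }

    treated = list(meta.index[meta["treatment"] == "nitrate"])
    control = list(
        meta.index[
            (meta["organ"] == "nodule")
            & (meta["sample_class"] == "whole_organ")
            & meta["treatment"].isin(["", "none"])
            & (meta["timepoint"] == 14)
        ]
    )
    if labels is not None and len(treated) >= 2 and len(control) >= 2:
        fam_map = pd.Series("other", index=labels.index, dtype=object)
        fam_map[labels["family"]] = "family"
        fam_map[labels["senescence_marker"]] = "senescence_marker"
        fam_map = fam_map[fam_map != "other"]
        if len(fam_map):
            response = screens_qc.senescence_response(
                compendium, control, treated, fam_map
            )
            out = response.ratios.copy()
            out.index.name = "gene_id"
            cio.write_table(out, outdir / "senescence_ratios.tsv", index=True)
            cio.write_table(
                response.family_summary, outdir / "senescence_summary.tsv", index=True
            )
            result["senescence"] = {
                family: {
                    "frac_down": _round(row["frac_down"]),
                    "frac_up": _round(row["frac_up"]),
                }
                for family, row in response.family_summary.iterrows()
            }
    return result


def _stage_qc(
    config: RunConfig,
    compendium: Compendium,
    labels: pd.DataFrame | None,
    family_genes: list[str],
    outdir: Path,
    qc_flags: list[str],
) -> dict[str, Any]:
    result: dict[str, Any] = {}
    contaminated: list[str] = []
    if labels is not None and labels["bacterial_marker"].any():
        markers = list(labels.index[labels["bacterial_marker"]])
        report = screens_qc.detect_contamination(
            compendium, markers, z_cut=config.z_cut
        )
        cio.write_table(report, outdir / "qc_contamination.tsv", index=True)
        contaminated = list(report.index[report["flagged"]])
        qc_flags.extend(contaminated)
        result["contamination_flags"] = contaminated
    if family_genes:
        relaxed = screens_qc.flag_relaxed_specificity(
            compendium,
            family_genes,
            floor_factor=config.floor_factor,
            ratio_cut=config.ratio_cut,
            exclude_conditions=contaminated,
        )
        cio.write_table(relaxed, outdir / "qc_relaxed.tsv", index=True)
        result["relaxed_flagged"] = sorted(relaxed.index[relaxed["flagged"]])
    return result
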