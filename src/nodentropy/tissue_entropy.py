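"""Shannon-entropy tissue specificity of expression profiles.

The analysis aggregates compendium conditions into ``N`` tissue classes
(the default panel has N = 10: leaf, petiole, stem, bud, flower, seed,
pod, root, nodule, mycorrhiza, with the nodule, seed and root classes
averaging several developmental stages / experiments), converts each
gene's tissue profile ``W_t`` to relative expression

    P_t = W_t / sum_t W_t

and scores specificity with the Shannon entropy

    E = -sum_t P_t * log2(P_t),      with 0 * log2(0) := 0.

``E`` ranges from 0 (all expression in a single tissue) to ``log2(N)``
(perfectly uniform expression).  Genes are ranked by increasing entropy
(rank 1 = most tissue specific); ties break lexicographically on gene id
so ranks are reproducible.  All-zero genes have no defined relative
profile and are excluded from the ranking rather than assigned maximal
entropy: a gene that is never expressed carries no specificity
information.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .compendium_io import Compendium, MappingError, ValidationError

__all__ = [
    "TissueMap",
    "TissueProfile",
    "RelativeProfile",
    "EntropyTable",
    "aggregate_tissues",
    "relative_expression",
    "shannon_entropy",
    "select_most_specific",
    "load_tissue_map",
    "reference_tissue_map",
    "default_tissue_map",
]


@dataclass
class TissueMap:
    """Ordered assignment of compendium conditions to tissue classes."""

    tissues: list[tuple[str, list[str]]]

    def __post_init__(self) -> None:
        if len(self.tissues) < 2:
            raise ValidationError("a tissue map needs at least two tissues")
        seen_tissue: set[str] = set()
        seen_cond: set[str] = set()
        for name, conds in self.tissues:
            if name in seen_tissue:
                raise ValidationError(f"duplicate tissue {name!r}")
            seen_tissue.add(name)
            if not conds:
                raise ValidationError(f"tissue {name!r} has no conditions")
            for c in conds:
                if c in seen_cond:
                    raise ValidationError(
                        f"condition {c!r} assigned to more than one tissue"
                    )
                seen_cond.add(c)

    @property
    def n(self) -> int:
        return len(self.tissues)

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.tissues]

    @property
    def n_conditions(self) -> int:
        return sum(len(conds) for _, conds in self.tissues)


@dataclass
class TissueProfile:
    """Gene x tissue matrix of mean signals W, in tissue-map order."""

    values: pd.DataFrame


@dataclass
class RelativeProfile:
    """Row-normalized profiles P; genes with all-zero W are undefined."""

    values: pd.DataFrame
    defined: pd.Series


@dataclass
class EntropyTable:
    """Per-gene entropy, specificity rank and dominant tissue."""

    frame: pd.DataFrame  # columns: entropy, rank, argmax_tissue

    @property
    def defined(self) -> pd.Series:
        return self.frame["entropy"].notna()


def aggregate_tissues(compendium: Compendium, tissue_map: TissueMap) -> TissueProfile:
    """Average the conditions of each tissue class (arithmetic mean)."""
    unknown = [
        c
        for _, conds in tissue_map.tissues
        for c in conds
        if c not in compendium.signals.columns
    ]
    if unknown:
        raise MappingError(f"tissue map names unknown condition(s): {unknown}")
    cols = {
        name: compendium.signals[conds].mean(axis=1)
        for name, conds in tissue_map.tissues
    }
    return TissueProfile(pd.DataFrame(cols, index=compendium.signals.index))


def relative_expression(profile: TissueProfile) -> RelativeProfile:
    """Row-normalize W to P; all-zero rows are flagged undefined."""
    w = profile.values
    totals = w.sum(axis=1)
    defined = totals > 0
    p = w.div(totals.where(defined), axis=0)
    p[~defined] = np.nan
    return RelativeProfile(p, defined)


def _entropy_rows(p: np.ndarray) -> np.ndarray:
    terms = np.zeros_like(p, dtype=float)
    pos = p > 0
    terms[pos] = -p[pos] * np.log2(p[pos])
    return terms.sum(axis=1)


def shannon_entropy(relative: RelativeProfile) -> EntropyTable:
    """Shannon entropy per gene, with stable specificity ranks."""
    p = relative.values.to_numpy(dtype=float)
    entropy = np.full(len(p), np.nan)
    mask = relative.defined.to_numpy()
    if mask.any():
        entropy[mask] = _entropy_rows(np.nan_to_num(p[mask]))
    frame = pd.DataFrame(index=relative.values.index)
    frame["entropy"] = entropy
    argmax = pd.Series(pd.NA, index=frame.index, dtype=object)
    if mask.any():
        argmax[relative.defined] = relative.values[relative.defined].idxmax(axis=1)
    frame["argmax_tissue"] = argmax

    defined_ids = frame.index[relative.defined]
    order = sorted(defined_ids, key=lambda g: (frame.at[g, "entropy"], g))
    rank = pd.Series(np.nan, index=frame.index)
    rank[order] = np.arange(1, len(order) + 1, dtype=float)
    frame["rank"] = rank
    return EntropyTable(frame)


def select_most_specific(table: EntropyTable, k: int) -> list[str]:
    """The ``k`` lowest-entropy genes (ties broken by gene id)."""
    defined = table.frame[table.frame["entropy"].notna()]
    if k > len(defined):
        raise ValueError(
            f"k={k} exceeds the {len(defined)} genes with defined entropy"
        )
    if k < 0:
        raise ValueError("k must be non-negative")
    ranked = defined.sort_values("rank")
    return list(ranked.index[:k])


# ---------------------------------------------------------------------------
# tissue-map construction
# ---------------------------------------------------------------------------


def load_tissue_map(path: Path | str) -> TissueMap:
    """Load a YAML tissue map: a list of ``{tissue: name, conditions: [...]}``."""
    with open(path, "r", encoding="utf-8") as fh:
        spec = yaml.safe_load(fh)
    return _map_from_spec(spec)


def _map_from_spec(spec) -> TissueMap:
    if not isinstance(spec, list):
        raise ValidationError("tissue map YAML must be a list of mappings")
    tissues = []
    for entry in spec:
        try:
            tissues.append((entry["tissue"], list(entry["conditions"])))
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"malformed tissue map entry: {entry!r}") from exc
    return TissueMap(tissues)


def reference_tissue_map() -> TissueMap:
    """The packaged 10-tissue / 19-experiment reference panel.

    Nodule pools the 4/10/14/28 dpi stages, seed pools six days-after-
    pollination stages, root pools the nodulation 0 dpi control and an
    independent experiment; the seven remaining tissues are single
    experiments.
    """
    ref = resources.files("nodentropy.data").joinpath("reference_tissue_panel.yaml")
    spec = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return _map_from_spec(spec)


def default_tissue_map(compendium: Compendium) -> TissueMap:
    """Derive the 10-tissue panel from compendium metadata.

    Whole-organ, untreated conditions only; the nodule class is restricted
    to the mature 4/10/14/28 dpi stages, mirroring the reference panel.
    Conditions whose organ is absent are skipped; at least two organ
    classes must remain.
    """
    meta = compendium.conditions
    whole = (meta["sample_class"] == "whole_organ") & (
        meta["treatment"].isin(["", "none"])
    )
    tissues: list[tuple[str, list[str]]] = []
    order = (
        "leaf",
        "petiole",
        "stem",
        "bud",
        "flower",
        "seed",
        "pod",
        "root",
        "nodule",
        "mycorrhiza",
    )
    for organ in order:
        sel = whole & (meta["organ"] == organ)
        if organ == "nodule":
            sel = sel & meta["timepoint"].isin([4, 10, 14, 28])
        conds = list(meta.index[sel])
        if conds:
            tissues.append((organ, conds))
    return TissueMap(tissues)
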