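"""Molecule records: parsing, filtering, label merging and normalization.

The input model mirrors drug-database exports: each compound carries a
SMILES string, a physicochemical feature block (1 Boolean, 5 integer and
7 float features by default) and a vector of binary ADMET outcomes.
Rule-based drug-likeness filters (Lipinski, Ghose, Veber, MDDR-like) are
declared in the schema only to be *excluded* from the inputs — they are
derived quantities, not measurements. Semantically redundant outcome
pairs are merged (intestinal absorption with Caco-2 permeability,
the two p-glycoprotein-inhibitor assays, the two hERG assays), leaving
21 final labels under the default schema.

JSON input format (one object per file)::

    {"id": "...", "smiles": "...",
     "properties": {"logp": 1.2, ...},
     "admet": {"ames_toxicity": 0, ...}}
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MoleculeRecord",
    "FeatureSchema",
    "MergeRule",
    "NormalizationStats",
    "default_schema",
    "parse_drugbank_json",
    "exclude_incomplete",
    "merge_labels",
    "fit_normalization",
    "apply_normalization",
    "records_to_frame",
    "frame_to_records",
    "write_records_csv",
    "read_records_csv",
    "feature_matrix",
    "label_matrix",
]


@dataclass(frozen=True)
class MergeRule:
    """Collapse `sources` into one label `target` with the given combiner.

    `op='or'` (default) marks the merged label positive if any source is —
    a conservative choice for safety liabilities such as hERG block.
    """

    sources: tuple[str, ...]
    target: str
    op: str = "or"  # 'or' | 'and' | 'first'

    def combine(self, values: list[int]) -> int:
        if self.op == "or":
            return int(any(values))
        if self.op == "and":
            return int(all(values))
        if self.op == "first":
            return int(values[0])
        raise ValueError(f"unknown merge op {self.op!r}")


_BOOL_FEATURES = ("bioavailability",)
_INT_FEATURES = (
    "physiological_charge",
    "hydrogen_acceptor_count",
    "hydrogen_donor_count",
    "rotatable_bond_count",
    "number_of_rings",
)
_FLOAT_FEATURES = (
    "logp",
    "logs",
    "pka",
    "water_solubility",
    "polar_surface_area",
    "molar_refractivity",
    "polarizability",
)
_EXCLUDED_FILTERS = ("lipinski_rule_of_five", "ghose_filter", "veber_rule", "mddr_like_rule")

_MERGE_RULES = (
    MergeRule(("human_intestinal_absorption", "caco2_permeability"), "human_intestinal_absorption"),
    MergeRule(("p_glycoprotein_inhibitor_i", "p_glycoprotein_inhibitor_ii"), "p_glycoprotein_inhibitor"),
    MergeRule(("herg_inhibition_i", "herg_inhibition_ii"), "herg_inhibition"),
)

# 21 final ADMET outcome names (absorption/distribution/metabolism/toxicity
# endpoints typical of predicted-ADMET tables); user-overridable.
_FINAL_LABELS = (
    "human_intestinal_absorption",
    "blood_brain_barrier",
    "p_glycoprotein_substrate",
    "p_glycoprotein_inhibitor",
    "renal_organic_cation_transporter",
    "cyp450_2c9_substrate",
    "cyp450_2d6_substrate",
    "cyp450_3a4_substrate",
    "cyp450_1a2_inhibitor",
    "cyp450_2c9_inhibitor",
    "cyp450_2d6_inhibitor",
    "cyp450_2c19_inhibitor",
    "cyp450_3a4_inhibitor",
    "cyp_inhibitory_promiscuity",
    "ames_toxicity",
    "carcinogenicity",
    "biodegradation",
    "herg_inhibition",
    "honey_bee_toxicity",
    "tetrahymena_pyriformis_toxicity",
    "micronucleus_test",
)


@dataclass(frozen=True)
class FeatureSchema:
    """Declares input feature names by kind, excluded filters and label merging."""

    bool_features: tuple[str, ...] = _BOOL_FEATURES
    int_features: tuple[str, ...] = _INT_FEATURES
    float_features: tuple[str, ...] = _FLOAT_FEATURES
    excluded_filter_names: tuple[str, ...] = _EXCLUDED_FILTERS
    merge_rules: tuple[MergeRule, ...] = _MERGE_RULES
    final_label_names: tuple[str, ...] = _FINAL_LABELS

    def __post_init__(self):
        overlap = set(self.excluded_filter_names) & set(self.input_feature_names)
        if overlap:
            raise ValueError(f"excluded filters appear among input features: {sorted(overlap)}")

    @property
    def input_feature_names(self) -> tuple[str, ...]:
        return self.bool_features + self.int_features + self.float_features

    @property
    def numeric_feature_names(self) -> tuple[str, ...]:
        return self.int_features + self.float_features

    @property
    def raw_label_names(self) -> tuple[str, ...]:
        merged_targets = {r.target for r in self.merge_rules}
        out: list[str] = []
        for name in self.final_label_names:
            if name in merged_targets:
                rule = next(r for r in self.merge_rules if r.target == name)
                out.extend(rule.sources)
            else:
                out.append(name)
        return tuple(out)

    @property
    def n_labels(self) -> int:
        return len(self.final_label_names)


def default_schema() -> FeatureSchema:
    return FeatureSchema()


@dataclass
class MoleculeRecord:
    """One compound: SMILES, feature block, and (optionally) binary labels.

    `labels` maps label name to 0/1 and may hold raw (pre-merge) or final
    names; `label_vector` orders the final names into an array.
    """

    id: str
    smiles: str
    bool_features: dict[str, bool] = field(default_factory=dict)
    int_features: dict[str, int] = field(default_factory=dict)
    float_features: dict[str, float] = field(default_factory=dict)
    labels: dict[str, int] | None = None

    def feature_value(self, name: str):
        for block in (self.bool_features, self.int_features, self.float_features):
            if name in block:
                return block[name]
        return None

    def is_complete(self, schema: FeatureSchema, require_labels: bool = True) -> bool:
        if not self.smiles:
            return False
        for name in schema.bool_features:
            if self.bool_features.get(name) is None:
                return False
        for name in schema.int_features:
            if self.int_features.get(name) is None:
                return False
        for name in schema.float_features:
            v = self.float_features.get(name)
            if v is None or not np.isfinite(v):
                return False
        if require_labels:
            if self.labels is None:
                return False
            names = schema.raw_label_names if set(schema.raw_label_names) <= set(self.labels) else schema.final_label_names
            for name in names:
                if self.labels.get(name) is None:
                    return False
        return True

    def label_vector(self, schema: FeatureSchema) -> np.ndarray:
        if self.labels is None:
            raise ValueError(f"record {self.id} has no labels")
        try:
            return np.array([int(self.labels[n]) for n in schema.final_label_names], dtype=np.int64)
        except KeyError as err:
            raise KeyError(f"record {self.id} missing final label {err}; run merge_labels first") from err


def parse_drugbank_json(paths: list[str | Path], schema: FeatureSchema | None = None) -> list[MoleculeRecord]:
    """Parse one-JSON-object-per-file exports into records, sorted by id.

    Properties named among the schema's excluded filters are dropped;
    property names unknown to the schema trigger a warning and are ignored.
    Malformed JSON is a hard error naming the offending file.
    """
    schema = schema or default_schema()
    records = []
    known = set(schema.input_feature_names)
    excluded = set(schema.excluded_filter_names)
    label_names = set(schema.raw_label_names) | set(schema.final_label_names)
    for path in paths:
        path = Path(path)
        try:
            obj = json.loads(path.read_text())
        except json.JSONDecodeError as err:
            raise ValueError(f"malformed JSON in {path}: {err}") from err
        props = obj.get("properties", {})
        rec = MoleculeRecord(id=str(obj.get("id", path.stem)), smiles=obj.get("smiles", ""))
        for name, value in props.items():
            if name in excluded or value is None:
                continue
            if name in schema.bool_features:
                rec.bool_features[name] = bool(value)
            elif name in schema.int_features:
                rec.int_features[name] = int(value)
            elif name in schema.float_features:
                rec.float_features[name] = float(value)
            elif name not in known:
                warnings.warn(f"{path.name}: unknown property {name!r} ignored", stacklevel=2)
        admet = obj.get("admet")
        if admet is not None:
            rec.labels = {}
            for name, value in admet.items():
                if name in label_names:
                    rec.labels[name] = int(value)
                else:
                    warnings.warn(f"{path.name}: unknown ADMET label {name!r} ignored", stacklevel=2)
        records.append(rec)
    records.sort(key=lambda r: r.id)
    return records


def exclude_incomplete(
    records: list[MoleculeRecord], schema: FeatureSchema | None = None, require_labels: bool = True
) -> list[MoleculeRecord]:
    """Drop records missing the SMILES, any input feature, or any label."""
    schema = schema or default_schema()
    kept = [r for r in records if r.is_complete(schema, require_labels=require_labels)]
    dropped = len(records) - len(kept)
    if dropped:
        logger.info("exclude_incomplete: dropped %d of %d records", dropped, len(records))
    return kept


def merge_labels(records: list[MoleculeRecord], schema: FeatureSchema | None = None) -> list[MoleculeRecord]:
    """Apply the schema's merge rules, producing final-name label dicts.

    Records whose labels already use final names pass through unchanged;
    a missing merge source is a hard error.
    """
    schema = schema or default_schema()
    out = []
    for rec in records:
        if rec.labels is None:
            out.append(rec)
            continue
        merged: dict[str, int] = {}
        consumed: set[str] = set()
        for rule in schema.merge_rules:
            # already merged: target present, no other source present (the
            # target may share its name with one of the sources, e.g. HIA)
            if rule.target in rec.labels and not any(s in rec.labels for s in rule.sources if s != rule.target):
                merged[rule.target] = int(rec.labels[rule.target])  # already merged
                consumed.add(rule.target)
                continue
            try:
                values = [int(rec.labels[s]) for s in rule.sources]
            except KeyError as err:
                raise KeyError(f"record {rec.id}: merge source {err} missing for target {rule.target!r}") from err
            merged[rule.target] = rule.combine(values)
            consumed.update(rule.sources)
        for name in schema.final_label_names:
            if name in merged:
                continue
            if name not in rec.labels:
                raise KeyError(f"record {rec.id}: label {name!r} missing")
            merged[name] = int(rec.labels[name])
        out.append(replace(rec, labels=merged))
    return out


@dataclass
class NormalizationStats:
    """Per-feature mean and standard deviation fitted on the training split."""

    means: dict[str, float]
    stds: dict[str, float]

    def save(self, path: str | Path):
        Path(path).write_text(json.dumps({"means": self.means, "stds": self.stds}, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "NormalizationStats":
        payload = json.loads(Path(path).read_text())
        return cls(means=payload["means"], stds=payload["stds"])


def fit_normalization(train_records: list[MoleculeRecord], schema: FeatureSchema | None = None) -> NormalizationStats:
    """Compute z-score statistics for the numeric features on training data only.

    A zero-variance feature is a hard error: it cannot be standardized and
    signals a degenerate split.
    """
    schema = schema or default_schema()
    means, stds = {}, {}
    for name in schema.numeric_feature_names:
        values = np.array([r.feature_value(name) for r in train_records], dtype=float)
        if values.size == 0 or np.any(~np.isfinite(values)):
            raise ValueError(f"feature {name!r}: missing values; run exclude_incomplete first")
        std = float(values.std())
        # relative tolerance: a constant feature leaves only rounding noise
        if values.size < 2 or std <= 1e-10 * max(1.0, float(np.abs(values).max())):
            raise ValueError(f"feature {name!r} has zero variance on the training split")
        means[name] = float(values.mean())
        stds[name] = std
    return NormalizationStats(means=means, stds=stds)


def apply_normalization(
    records: list[MoleculeRecord], stats: NormalizationStats, schema: FeatureSchema | None = None
) -> list[MoleculeRecord]:
    """Return records with z-scored numeric features; Booleans untouched."""
    schema = schema or default_schema()
    out = []
    for rec in records:
        ints = {n: (rec.int_features[n] - stats.means[n]) / stats.stds[n] for n in schema.int_features}
        floats = {n: (rec.float_features[n] - stats.means[n]) / stats.stds[n] for n in schema.float_features}
        # normalized integers become reals; they live on as float features of the record
        out.append(replace(rec, int_features=ints, float_features=floats))
    return out


# -- tabular round trip -------------------------------------------------------


def records_to_frame(records: list[MoleculeRecord], schema: FeatureSchema | None = None) -> pd.DataFrame:
    schema = schema or default_schema()
    rows = []
    any_labels = any(r.labels is not None for r in records)
    for rec in records:
        row: dict = {"id": rec.id, "smiles": rec.smiles}
        for name in schema.bool_features:
            v = rec.bool_features.get(name)
            row[name] = int(v) if v is not None else np.nan
        for name in schema.int_features:
            row[name] = rec.int_features.get(name, np.nan)
        for name in schema.float_features:
            row[name] = rec.float_features.get(name, np.nan)
        if any_labels:
            label_names = schema.final_label_names if rec.labels and set(schema.final_label_names) <= set(rec.labels) else schema.raw_label_names
            for name in label_names:
                row[name] = (rec.labels or {}).get(name, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame, schema: FeatureSchema | None = None) -> list[MoleculeRecord]:
    schema = schema or default_schema()
    label_cols = [c for c in frame.columns if c in set(schema.raw_label_names) | set(schema.final_label_names)]
    records = []
    for _, row in frame.iterrows():
        rec = MoleculeRecord(id=str(row["id"]), smiles=str(row["smiles"]))
        for name in schema.bool_features:
            if name in frame.columns and pd.notna(row[name]):
                rec.bool_features[name] = bool(int(row[name]))
        for name in schema.int_features:
            if name in frame.columns and pd.notna(row[name]):
                v = float(row[name])
                rec.int_features[name] = int(v) if float(v).is_integer() else v
        for name in schema.float_features:
            if name in frame.columns and pd.notna(row[name]):
                rec.float_features[name] = float(row[name])
        if label_cols:
            labels = {c: int(row[c]) for c in label_cols if pd.notna(row[c])}
            rec.labels = labels or None
        records.append(rec)
    return records


def write_records_csv(records: list[MoleculeRecord], path: str | Path, schema: FeatureSchema | None = None):
    records_to_frame(records, schema).to_csv(path, index=False)


def read_records_csv(path: str | Path, schema: FeatureSchema | None = None) -> list[MoleculeRecord]:
    return frame_to_records(pd.read_csv(path), schema)


# -- matrices for the models --------------------------------------------------


def feature_matrix(records: list[MoleculeRecord], schema: FeatureSchema | None = None) -> pd.DataFrame:
    """Feature block as a DataFrame indexed by record id, plus the smiles column."""
    schema = schema or default_schema()
    frame = records_to_frame(records, schema)
    cols = ["smiles"] + list(schema.input_feature_names)
    return frame.set_index(frame["id"].astype(str))[cols]


def label_matrix(records: list[MoleculeRecord], schema: FeatureSchema | None = None) -> np.ndarray:
    schema = schema or default_schema()
    return np.stack([r.label_vector(schema) for r in records])
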