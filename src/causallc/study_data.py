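"""Study design declaration and cohort ingestion.

A study is described by an ordered sequence of treatment *blocks* (e.g.
preoperative, intraoperative, postoperative bundles of interventions),
confounders that may drive compliance with every block or only with later
blocks, external covariates that act on the outcomes directly, and one or
more named *outcome sets* whose binary items are partitioned into latent
dimensions (e.g. a "complications" dimension and a "discharge-timing"
dimension).

The design is declared in a YAML config; columns are never inferred from the
data.  Cohorts are plain CSV tables with a header row, one row per patient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("causallc")

BINARY = "binary"
CONTINUOUS = "continuous"


class ConfigurationError(ValueError):
    """The design config is internally inconsistent or refers to unknown columns."""


class ValidationError(ValueError):
    """A data row violates the declared column contract."""


@dataclass(frozen=True)
class TreatmentBlock:
    """One ordered block of treatments (index starts at 1)."""

    index: int
    treatments: tuple[tuple[str, str], ...]  # (name, kind)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.treatments)

    def kind(self, name: str) -> str:
        for t, k in self.treatments:
            if t == name:
                return k
        raise KeyError(name)


@dataclass(frozen=True)
class OutcomeSpec:
    """Binary outcome items partitioned into named latent dimensions."""

    dimensions: tuple[tuple[str, tuple[str, ...]], ...]  # (dim name, items)

    @property
    def items(self) -> tuple[str, ...]:
        return tuple(o for _, outs in self.dimensions for o in outs)

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def n_dimensions(self) -> int:
        return len(self.dimensions)

    def dimension_index(self) -> np.ndarray:
        """0-based dimension index per item, in item order."""
        idx = []
        for d, (_, outs) in enumerate(self.dimensions):
            idx.extend([d] * len(outs))
        return np.asarray(idx, dtype=int)


@dataclass(frozen=True)
class StudyDesign:
    """Complete column contract binding a cohort table to the causal diagram."""

    blocks: tuple[TreatmentBlock, ...]
    confounders_all: tuple[str, ...]
    # (column, first block index whose treatments it may predict)
    confounders_post: tuple[tuple[str, int], ...]
    external_covariates: tuple[str, ...]
    outcome_sets: Mapping[str, OutcomeSpec]
    # continuous (non 0/1) confounder / covariate columns
    continuous_columns: tuple[str, ...] = ()
    id_column: str = "id"

    def __post_init__(self) -> None:
        indices = [b.index for b in self.blocks]
        if indices != list(range(1, len(self.blocks) + 1)):
            raise ConfigurationError(
                f"block indices must be contiguous from 1, got {indices}"
            )
        seen: set[str] = set()
        for group in (
            self.treatment_names(),
            self.confounders_all,
            tuple(c for c, _ in self.confounders_post),
            self.external_covariates,
            self.outcome_names(),
        ):
            for col in group:
                if col in seen:
                    raise ConfigurationError(
                        f"column {col!r} declared in more than one role"
                    )
                seen.add(col)
        for name, spec in self.outcome_sets.items():
            if spec.n_dimensions < 1 or any(not outs for _, outs in spec.dimensions):
                raise ConfigurationError(
                    f"outcome set {name!r} must have >=1 nonempty dimensions"
                )

    # -- column views -------------------------------------------------------
    def treatment_names(self) -> tuple[str, ...]:
        return tuple(t for b in self.blocks for t in b.names)

    def treatment_kind(self, name: str) -> str:
        for b in self.blocks:
            if name in b.names:
                return b.kind(name)
        raise KeyError(name)

    def outcome_names(self) -> tuple[str, ...]:
        return tuple(o for s in self.outcome_sets.values() for o in s.items)

    def binary_columns(self) -> tuple[str, ...]:
        binary = [
            t for b in self.blocks for t, k in b.treatments if k == BINARY
        ]
        cont = set(self.continuous_columns)
        binary += [c for c in self.confounders_all if c not in cont]
        binary += [c for c, _ in self.confounders_post if c not in cont]
        binary += [c for c in self.external_covariates if c not in cont]
        binary += list(self.outcome_names())
        return tuple(binary)

    def declared_columns(self) -> tuple[str, ...]:
        return (
            self.confounders_all
            + tuple(c for c, _ in self.confounders_post)
            + self.treatment_names()
            + self.external_covariates
            + self.outcome_names()
        )

    def predictors_for_block(self, v: int) -> list[str]:
        """Predictors of block-v treatments: confounders available at block v
        plus every treatment of earlier blocks (the arrows of the diagram)."""
        cols = list(self.confounders_all)
        cols += [c for c, entry in self.confounders_post if entry <= v]
        for b in self.blocks:
            if b.index < v:
                cols += list(b.names)
        return cols


@dataclass
class PatientRecord:
    """One patient: confounders, block-ordered treatments, covariates, outcomes."""

    id: object
    confounders: dict[str, float]
    treatments: dict[str, float]
    external: dict[str, float]
    outcomes: dict[str, dict[str, int]]  # outcome set -> item -> 0/1

    def value(self, column: str) -> float:
        for pool in (self.confounders, self.treatments, self.external):
            if column in pool:
                return pool[column]
        for items in self.outcomes.values():
            if column in items:
                return items[column]
        raise KeyError(column)


# ---------------------------------------------------------------------------
# Config parsing
# ---------------------------------------------------------------------------

def load_design(design_path: str | Path) -> StudyDesign:
    """Parse a YAML design config into a :class:`StudyDesign`."""
    with open(design_path) as fh:
        raw = yaml.safe_load(fh)
    try:
        blocks = tuple(
            TreatmentBlock(
                index=int(b["index"]),
                treatments=tuple(
                    (t["name"], t.get("kind", BINARY)) for t in b["treatments"]
                ),
            )
            for b in raw["blocks"]
        )
        confounders_post = tuple(
            (c["name"], int(c["enters_at_block"]))
            for c in raw.get("confounders_post", [])
        )
        outcome_sets = {
            name: OutcomeSpec(
                dimensions=tuple(
                    (dname, tuple(items)) for dname, items in spec.items()
                )
            )
            for name, spec in raw["outcome_sets"].items()
        }
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"malformed design config: {exc}") from exc
    for b in blocks:
        for _, kind in b.treatments:
            if kind not in (BINARY, CONTINUOUS):
                raise ConfigurationError(f"unknown treatment kind {kind!r}")
    return StudyDesign(
        blocks=blocks,
        confounders_all=tuple(raw.get("confounders_all", [])),
        confounders_post=confounders_post,
        external_covariates=tuple(raw.get("external_covariates", [])),
        outcome_sets=outcome_sets,
        continuous_columns=tuple(raw.get("continuous_columns", [])),
        id_column=raw.get("id_column", "id"),
    )


# ---------------------------------------------------------------------------
# Cohort ingestion
# ---------------------------------------------------------------------------

def _records_from_frame(df: pd.DataFrame, design: StudyDesign) -> list[PatientRecord]:
    records = []
    conf_cols = design.confounders_all + tuple(c for c, _ in design.confounders_post)
    for _, row in df.iterrows():
        rec = PatientRecord(
            id=row[design.id_column] if design.id_column in df.columns else row.name,
            confounders={c: float(row[c]) for c in conf_cols},
            treatments={t: float(row[t]) for t in design.treatment_names()},
            external={c: float(row[c]) for c in design.external_covariates},
            outcomes={
                name: {o: int(row[o]) for o in spec.items}
                for name, spec in design.outcome_sets.items()
            },
        )
        records.append(rec)
    return records


def load_cohort(
    table_path: str | Path, design_path: str | Path
) -> tuple[list[PatientRecord], StudyDesign]:
    """Read and validate a cohort CSV against its design config.

    Rows with missing values in any declared column are rejected (counted and
    logged, never imputed).  Non-binary values in declared-binary columns are
    a hard validation error naming the offending row.
    """
    design = load_design(design_path)
    df = pd.read_csv(table_path)
    missing_cols = [c for c in design.declared_columns() if c not in df.columns]
    if missing_cols:
        raise ConfigurationError(
            f"config declares columns absent from the table: {missing_cols}"
        )

    declared = list(design.declared_columns())
    complete = df[declared].notna().all(axis=1)
    n_rejected = int((~complete).sum())
    if n_rejected:
        logger.warning("rejected %d rows with missing declared values", n_rejected)
    kept = df.loc[complete].copy()
    logger.info("accepted %d rows, rejected %d rows", len(kept), n_rejected)

    for col in design.binary_columns():
        bad = ~kept[col].isin([0, 1])
        if bad.any():
            row_id = (
                kept.loc[bad, design.id_column].iloc[0]
                if design.id_column in kept.columns
                else kept.index[bad][0]
            )
            raise ValidationError(
                f"non-binary value in binary column {col!r} (row id {row_id})"
            )
    for col in declared:
        if not np.isfinite(kept[col].to_numpy(dtype=float)).all():
            raise ValidationError(f"non-finite value in column {col!r}")

    return _records_from_frame(kept, design), design


def records_to_frame(records: Sequence[PatientRecord], design: StudyDesign) -> pd.DataFrame:
    """Flatten records back to a table with the declared columns."""
    rows = []
    for rec in records:
        row: dict[str, object] = {design.id_column: rec.id}
        row.update(rec.confounders)
        row.update(rec.treatments)
        row.update(rec.external)
        for items in rec.outcomes.values():
            row.update(items)
        rows.append(row)
    cols = [design.id_column, *design.declared_columns()]
    return pd.DataFrame(rows, columns=cols)


def write_cohort(
    records: Sequence[PatientRecord], design: StudyDesign, path: str | Path
) -> None:
    records_to_frame(records, design).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Descriptive summary
# ---------------------------------------------------------------------------

def summarize_cohort(
    records: Sequence[PatientRecord],
    design: StudyDesign,
    columns: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-column frequency summary.

    Binary columns are reported as ``n (percent)``; continuous columns as
    mean and sample standard deviation (n−1 denominator).
    """
    if not records:
        raise ValueError("empty cohort")
    df = records_to_frame(records, design)
    binary = set(design.binary_columns())
    cols = list(columns) if columns is not None else list(design.declared_columns())
    out = []
    for col in cols:
        vals = df[col].to_numpy(dtype=float)
        if col in binary:
            n1 = int(vals.sum())
            pct = 100.0 * n1 / len(vals)
            out.append(
                {"column": col, "kind": BINARY, "n": n1, "percent": pct,
                 "mean": np.nan, "sd": np.nan,
                 "display": f"{n1} ({pct:.2f}%)"}
            )
        else:
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
            out.append(
                {"column": col, "kind": CONTINUOUS, "n": len(vals),
                 "percent": np.nan, "mean": mean, "sd": sd,
                 "display": f"{mean:.2f} ± {sd:.2f}"}
            )
    return pd.DataFrame(
        out, columns=["column", "kind", "n", "percent", "mean", "sd", "display"]
    )
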