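"""Design-matrix construction for the two-equation ordered-probit model.

The model keeps two strictly disjoint covariate sets: the *latent* set
(health-condition indicators and their screened interactions, which drive
the continuous latent health index) and the *threshold* set (reporting
covariates, which shift the cut-points between response categories).
Disjointness is what identifies reporting behaviour separately from
health, so it is enforced at construction time and re-checked after every
reallocation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TableSchema",
    "RespondentTable",
    "LatentDesign",
    "ThresholdDesign",
    "screen_interactions",
    "build_latent_design",
    "build_threshold_design",
    "reallocate_covariates",
]


class DesignError(ValueError):
    """Raised when a design specification is inconsistent."""


@dataclass(frozen=True)
class TableSchema:
    """Column mapping for a respondent-level survey table.

    Parameters
    ----------
    outcomes
        Mapping from dimension label (e.g. ``"Mobility"``) to the column
        holding the ordinal response coded 1 (no problems) .. 5 (extreme).
    conditions
        Binary long-term-condition indicator columns.
    limitation
        Column holding the recent-limitation response with levels
        ``"a_lot"``, ``"a_little"``, ``"no"`` (reference).
    families
        Mapping from family name to the list of mutually exclusive dummy
        columns forming that family (baseline column included).
    baselines
        Mapping from family name to the column treated as baseline and
        dropped from the threshold design.
    weight
        Survey-weight column (non-negative, positive sum).
    """

    outcomes: dict[str, str]
    conditions: tuple[str, ...]
    limitation: str
    families: dict[str, tuple[str, ...]]
    baselines: dict[str, str]
    weight: str

    def __post_init__(self) -> None:
        for fam, base in self.baselines.items():
            if fam not in self.families:
                raise DesignError(f"baseline given for unknown family {fam!r}")
            if base not in self.families[fam]:
                raise DesignError(
                    f"baseline column {base!r} not in family {fam!r}"
                )


LIMITATION_LEVELS = ("a_lot", "a_little", "no")
LIMITATION_REFERENCE = "no"


@dataclass
class RespondentTable:
    """A validated respondent table plus its schema.

    Rows with a missing value in any modelled field are dropped on
    construction (complete-case analysis); the count is logged and kept
    in :attr:`n_dropped`.
    """

    data: pd.DataFrame
    schema: TableSchema
    n_dropped: int = 0

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, schema: TableSchema) -> "RespondentTable":
        used = cls._used_columns(schema)
        missing_cols = [c for c in used if c not in frame.columns]
        if missing_cols:
            raise DesignError(f"table lacks declared columns: {missing_cols}")
        sub = frame.loc[:, used]
        complete = sub.notna().all(axis=1)
        n_dropped = int((~complete).sum())
        if n_dropped:
            logger.info("dropped %d rows with missing modelled fields", n_dropped)
        data = frame.loc[complete].reset_index(drop=True)
        table = cls(data=data, schema=schema, n_dropped=n_dropped)
        table.validate()
        return table

    @staticmethod
    def _used_columns(schema: TableSchema) -> list[str]:
        cols: list[str] = list(schema.outcomes.values())
        cols += list(schema.conditions)
        cols.append(schema.limitation)
        for fam_cols in schema.families.values():
            cols += list(fam_cols)
        cols.append(schema.weight)
        seen: set[str] = set()
        out = []
        for c in cols:
            if c not in seen:
                seen.add(c)
                out.append(c)
        return out

    def validate(self) -> None:
        df, sc = self.data, self.schema
        for dim, col in sc.outcomes.items():
            vals = df[col].to_numpy()
            if not np.isin(vals, [1, 2, 3, 4, 5]).all():
                raise DesignError(
                    f"outcome column {col!r} ({dim}) has levels outside 1..5"
                )
        for col in list(sc.conditions) + [
            c for fam in sc.families.values() for c in fam
        ]:
            vals = df[col].to_numpy()
            if not np.isin(vals, [0, 1]).all():
                raise DesignError(f"indicator column {col!r} is not binary 0/1")
        lim = df[sc.limitation]
        bad = ~lim.isin(LIMITATION_LEVELS)
        if bad.any():
            raise DesignError(
                f"limitation column {sc.limitation!r} has levels outside "
                f"{LIMITATION_LEVELS}"
            )
        w = df[sc.weight].to_numpy(dtype=float)
        if (w < 0).any():
            raise DesignError("survey weights must be non-negative")
        if w.sum() <= 0:
            raise DesignError("survey weights must have positive sum")
        for fam, cols in sc.families.items():
            if len(cols) == 1:
                continue  # single-indicator family: binary already checked
            rowsum = df[list(cols)].to_numpy().sum(axis=1)
            if not (rowsum == 1).all():
                idx = int(np.flatnonzero(rowsum != 1)[0])
                raise DesignError(
                    f"family {fam!r} is not one-hot at row {idx} "
                    f"(row sum {rowsum[idx]})"
                )

    @property
    def weights(self) -> np.ndarray:
        return self.data[self.schema.weight].to_numpy(dtype=float)

    def outcome(self, dimension: str) -> np.ndarray:
        col = self.schema.outcomes[dimension]
        return self.data[col].to_numpy(dtype=int)

    @property
    def n_obs(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class LatentDesign:
    """Design matrix for the latent health index.

    ``provenance[k]`` is either ``("main", name)`` for a main effect or
    ``("interaction", parents)`` for a product column.
    """

    matrix: np.ndarray
    column_names: tuple[str, ...]
    provenance: tuple[tuple, ...]

    def __post_init__(self) -> None:
        if len(self.column_names) != len(set(self.column_names)):
            raise DesignError("duplicate column names in latent design")
        if self.matrix.shape[1] != len(self.column_names):
            raise DesignError("latent matrix / names mismatch")

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class ThresholdDesign:
    """Design matrix for the cut-point (reporting) equation.

    ``group_block`` names the columns of the focal contrast family, e.g.
    the non-baseline ethnic-group dummies.
    """

    matrix: np.ndarray
    column_names: tuple[str, ...]
    group_block: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.column_names) != len(set(self.column_names)):
            raise DesignError("duplicate column names in threshold design")
        if self.matrix.shape[1] != len(self.column_names):
            raise DesignError("threshold matrix / names mismatch")
        unknown = set(self.group_block) - set(self.column_names)
        if unknown:
            raise DesignError(f"group block columns not in design: {sorted(unknown)}")

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def group_indices(self) -> np.ndarray:
        idx = {c: i for i, c in enumerate(self.column_names)}
        return np.array([idx[c] for c in self.group_block], dtype=int)


def _check_disjoint(latent_names, threshold_names) -> None:
    overlap = set(latent_names) & set(threshold_names)
    if overlap:
        raise DesignError(
            "latent and threshold designs share columns "
            f"{sorted(overlap)}; a covariate may enter only one equation "
            "(the disjointness rule that identifies reporting behaviour)"
        )


def screen_interactions(
    conditions: pd.DataFrame,
    weights: np.ndarray | None = None,
    max_order: int = 3,
    min_prevalence: float = 0.01,
    weighted: bool = True,
) -> list[tuple[str, ...]]:
    """Select condition interactions by joint (co-occurrence) prevalence.

    Returns every 2-way and (for ``max_order=3``) 3-way combination of
    condition columns whose joint prevalence — the weighted share of rows
    with all parents equal to 1 — is at least ``min_prevalence``. Each
    order is screened on its own joint prevalence; a triple can pass even
    if one of its sub-pairs does not. Ordering is lexicographic by parent
    names, so output is independent of row order.
    """
    if max_order not in (2, 3):
        raise DesignError("max_order must be 2 or 3")
    if not (0.0 < min_prevalence < 1.0):
        raise DesignError("min_prevalence must lie strictly in (0, 1)")
    mat = conditions.to_numpy()
    for j, col in enumerate(conditions.columns):
        if not np.isin(mat[:, j], [0, 1]).all():
            raise DesignError(f"condition column {col!r} is not binary 0/1")
    n = mat.shape[0]
    if weights is None or not weighted:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape[0] != n:
            raise DesignError("weights do not conform to condition rows")
    total = w.sum()
    if total <= 0:
        raise DesignError("weights must have positive sum")

    names = sorted(conditions.columns)
    colidx = {c: conditions.columns.get_loc(c) for c in names}
    selected: list[tuple[str, ...]] = []
    for order in range(2, max_order + 1):
        for combo in itertools.combinations(names, order):
            joint = np.ones(n, dtype=bool)
            for c in combo:
                joint &= mat[:, colidx[c]] == 1
            prev = w[joint].sum() / total
            if prev >= min_prevalence:
                selected.append(combo)
    return selected


def build_latent_design(
    table: RespondentTable,
    interactions: list[tuple[str, ...]] | None = None,
) -> LatentDesign:
    """Assemble the latent-health design matrix.

    Columns are the condition main effects, two recent-limitation dummies
    ("a lot", "a little"; reference "no"), and one product column per
    screened interaction.
    """
    interactions = interactions or []
    sc = table.schema
    df = table.data
    cols: list[np.ndarray] = []
    names: list[str] = []
    prov: list[tuple] = []
    for c in sc.conditions:
        cols.append(df[c].to_numpy(dtype=float))
        names.append(c)
        prov.append(("main", c))
    for level in ("a_lot", "a_little"):
        cols.append((df[sc.limitation] == level).to_numpy(dtype=float))
        names.append(f"limitation_{level}")
        prov.append(("main", f"limitation_{level}"))
    for combo in interactions:
        unknown = [c for c in combo if c not in sc.conditions]
        if unknown:
            raise DesignError(
                f"interaction parents {unknown} are not condition columns"
            )
        prod = np.ones(len(df))
        for c in combo:
            prod = prod * df[c].to_numpy(dtype=float)
        cols.append(prod)
        names.append(":".join(combo))
        prov.append(("interaction", tuple(combo)))
    matrix = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return LatentDesign(matrix=matrix, column_names=tuple(names), provenance=tuple(prov))


def build_threshold_design(
    table: RespondentTable,
    families: list[str] | None = None,
    contrast_family: str | None = None,
    latent: LatentDesign | None = None,
) -> ThresholdDesign:
    """Assemble the cut-point design matrix from dummy families.

    Each family's baseline column is dropped; the remaining dummies enter
    as-is. ``contrast_family`` marks the family whose non-baseline dummies
    form the group block used for threshold contrasts. When ``latent`` is
    given, disjointness with it is verified.
    """
    sc = table.schema
    df = table.data
    if families is None:
        families = list(sc.families)
    names: list[str] = []
    cols: list[np.ndarray] = []
    group_block: tuple[str, ...] = ()
    for fam in families:
        if fam not in sc.families:
            raise DesignError(f"unknown covariate family {fam!r}")
        base = sc.baselines.get(fam)
        if base is None and len(sc.families[fam]) > 1:
            raise DesignError(f"family {fam!r} has no declared baseline")
        fam_cols = [c for c in sc.families[fam] if c != base]
        for c in fam_cols:
            names.append(c)
            cols.append(df[c].to_numpy(dtype=float))
        if fam == contrast_family:
            group_block = tuple(fam_cols)
    if contrast_family is not None and not group_block:
        raise DesignError(
            f"contrast family {contrast_family!r} not among requested families"
        )
    matrix = np.column_stack(cols) if cols else np.empty((len(df), 0))
    design = ThresholdDesign(
        matrix=matrix, column_names=tuple(names), group_block=group_block
    )
    if latent is not None:
        _check_disjoint(latent.column_names, design.column_names)
    return design


def reallocate_covariates(
    latent: LatentDesign,
    threshold: ThresholdDesign,
    move: list[str],
) -> tuple[LatentDesign, ThresholdDesign]:
    """Move named columns from the threshold design into the latent design.

    Used for sensitivity specifications in which age/sex, deprivation or
    healthcare-use covariates are treated as determinants of latent health
    rather than of reporting. Moving a group-block column is refused: the
    threshold contrast is undefined without its family.
    """
    if not move:
        return latent, threshold
    unknown = [c for c in move if c not in threshold.column_names]
    if unknown:
        raise DesignError(f"cannot move unknown threshold columns {unknown}")
    blocked = [c for c in move if c in threshold.group_block]
    if blocked:
        raise DesignError(
            f"refusing to move contrast-family columns {blocked} out of the "
            "threshold design; the group contrast would be undefined"
        )
    keep = [i for i, c in enumerate(threshold.column_names) if c not in move]
    take = [i for i, c in enumerate(threshold.column_names) if c in move]
    new_threshold = ThresholdDesign(
        matrix=threshold.matrix[:, keep],
        column_names=tuple(threshold.column_names[i] for i in keep),
        group_block=threshold.group_block,
    )
    new_latent = LatentDesign(
        matrix=np.column_stack([latent.matrix, threshold.matrix[:, take]]),
        column_names=latent.column_names
        + tuple(threshold.column_names[i] for i in take),
        provenance=latent.provenance
        + tuple(("main", threshold.column_names[i]) for i in take),
    )
    _check_disjoint(new_latent.column_names, new_threshold.column_names)
    return new_latent, new_threshold
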