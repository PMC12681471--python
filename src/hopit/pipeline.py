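"""End-to-end runner: table in, fitted models and report tables out.

One :func:`run` call covers a full analysis: build the two design
matrices (with the interaction prevalence screen), fit the model for each
requested outcome dimension, compute fit metrics and group threshold
contrasts with parametric-bootstrap intervals, and write everything to an
output directory together with a machine-readable manifest. Sensitivity
specifications (main-effects-only, or reporting covariates moved into the
latent equation) are expressed in the same config and compared with
:func:`compare_specifications`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contrasts import bootstrap_contrasts, build_profiles, contrast_table, export_bubble_table
from .designs import (
    DesignError,
    RespondentTable,
    TableSchema,
    build_latent_design,
    build_threshold_design,
    reallocate_covariates,
    screen_interactions,
)
from .metrics import fit_report, report_table
from .model import fit
from .simulate import SyntheticConfig, generate

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run", "compare_specifications", "load_table"]


@dataclass
class RunConfig:
    """Declarative description of one analysis run."""

    output_dir: str
    input_path: str | None = None
    schema: TableSchema | None = None
    synthetic: SyntheticConfig | None = None
    dimensions: list[str] = field(default_factory=list)
    max_order: int = 3
    min_prevalence: float = 0.01
    weighted_screen: bool = True
    contrast_family: str = "group"
    n_draws: int = 1000
    seed: int = 0
    specification: str = "full"      # "full" | "main_effects"
    reallocate: list[str] = field(default_factory=list)
    row_filter: str | None = None    # pandas query, e.g. an age eligibility rule

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError(
                "exactly one of input_path and synthetic must be given"
            )
        if self.specification not in ("full", "main_effects"):
            raise ValueError(f"unknown specification {self.specification!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        schema = None
        if "schema" in raw:
            s = raw.pop("schema")
            schema = TableSchema(
                outcomes=s["outcomes"],
                conditions=tuple(s["conditions"]),
                limitation=s["limitation"],
                families={k: tuple(v) for k, v in s["families"].items()},
                baselines=s["baselines"],
                weight=s["weight"],
            )
        synthetic = None
        if "synthetic" in raw:
            synthetic = SyntheticConfig(**raw.pop("synthetic"))
        return cls(schema=schema, synthetic=synthetic, **raw)


def load_table(config: RunConfig) -> RespondentTable:
    if config.synthetic is not None:
        synth = generate(config.synthetic)
        table = synth.table
    else:
        if config.schema is None:
            raise DesignError("a schema is required to read a delimited table")
        frame = pd.read_csv(config.input_path)
        table = RespondentTable.from_frame(frame, config.schema)
    if config.row_filter:
        kept = table.data.query(config.row_filter).reset_index(drop=True)
        logger.info(
            "row filter %r kept %d of %d rows",
            config.row_filter, len(kept), len(table.data),
        )
        table = RespondentTable(
            data=kept, schema=table.schema, n_dropped=table.n_dropped
        )
        table.validate()
    return table


def _build_designs(table: RespondentTable, config: RunConfig):
    if config.specification == "main_effects":
        interactions: list[tuple[str, ...]] = []
    else:
        interactions = screen_interactions(
            table.data[list(table.schema.conditions)],
            table.weights,
            max_order=config.max_order,
            min_prevalence=config.min_prevalence,
            weighted=config.weighted_screen,
        )
    logger.info("interaction screen kept %d terms", len(interactions))
    latent = build_latent_design(table, interactions)
    threshold = build_threshold_design(
        table, contrast_family=config.contrast_family, latent=latent
    )
    if config.reallocate:
        latent, threshold = reallocate_covariates(
            latent, threshold, config.reallocate
        )
    return latent, threshold, interactions


def run(config: RunConfig) -> dict:
    """Execute one configured analysis and write its result bundle.

    Writes, per dimension: the fitted model (JSON), a coefficient table
    and a contrast table (CSV); plus a combined report table, the long
    bubble-plot export, and ``manifest.json``. Returns a summary dict with
    paths and convergence status.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = load_table(config)
    dimensions = config.dimensions or list(table.schema.outcomes)
    latent, threshold, interactions = _build_designs(table, config)
    weights = table.weights

    reports = []
    contrasts_by_dim = {}
    statuses = {}
    rng = np.random.default_rng(config.seed)
    for dim in dimensions:
        outcome = table.outcome(dim)
        fitted = fit(latent, threshold, outcome, weights, dimension=dim)
        statuses[dim] = bool(fitted.converged)
        slug = dim.lower().replace("/", "_").replace(" ", "_").replace("-", "_")
        fitted.to_json(out / f"fit_{slug}.json")
        se = np.sqrt(np.clip(np.diag(fitted.vcov), 0, None))
        pd.DataFrame(
            {
                "parameter": fitted.parameter_names,
                "estimate": fitted.params.pack(),
                "se": se,
            }
        ).to_csv(out / f"coefficients_{slug}.csv", index=False)
        reports.append(fit_report(fitted, latent, threshold, outcome, weights))
        profiles = build_profiles(threshold, weights)
        contrasts = bootstrap_contrasts(
            fitted,
            profiles,
            n_draws=config.n_draws,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        contrasts_by_dim[dim] = contrasts
        contrast_table(contrasts).to_csv(
            out / f"contrasts_{slug}.csv", index=False
        )

    report_table(reports).to_csv(out / "report_table.csv")
    bubble = export_bubble_table(contrasts_by_dim)
    bubble.to_csv(out / "bubble_table.csv", index=False)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "n_draws": config.n_draws,
        "specification": config.specification,
        "reallocate": config.reallocate,
        "dimensions": dimensions,
        "n_obs": table.n_obs,
        "n_dropped_missing": table.n_dropped,
        "n_interactions": len(interactions),
        "interactions": [list(t) for t in interactions],
        "converged": statuses,
        "min_prevalence": config.min_prevalence,
        "weighted_screen": config.weighted_screen,
        "contrast_family": config.contrast_family,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    if not all(statuses.values()):
        (out / "FAILED").write_text(
            "non-converged dimensions: "
            + ", ".join(d for d, ok in statuses.items() if not ok)
            + "\n"
        )
    return {
        "output_dir": str(out),
        "converged": statuses,
        "bubble_rows": len(bubble),
        "n_interactions": len(interactions),
    }


def compare_specifications(configs: list[RunConfig]) -> pd.DataFrame:
    """Run several specifications and align their threshold contrasts.

    Returns a long table with one row per (specification, dimension,
    group, boundary) plus a ``sign_change`` flag marking rows whose
    significant contrast has the opposite sign of the first (reference)
    specification's significant contrast — the headline sensitivity
    readout.
    """
    if not configs:
        raise ValueError("no specifications given")
    fams = {c.contrast_family for c in configs}
    if len(fams) != 1:
        raise ValueError("specifications must share the contrast family")
    frames = []
    for k, config in enumerate(configs):
        label = config.specification
        if config.reallocate:
            label += "+realloc"
        run(config)
        bubble = pd.read_csv(Path(config.output_dir) / "bubble_table.csv")
        bubble.insert(0, "spec", f"{k}:{label}")
        frames.append(bubble)
    combined = pd.concat(frames, ignore_index=True)
    ref = frames[0].set_index(["dimension", "group", "boundary"])
    flags = []
    for _, row in combined.iterrows():
        r = ref.loc[(row["dimension"], row["group"], row["boundary"])]
        flags.append(
            bool(
                row["significant"]
                and r["significant"]
                and row["sign"] != 0
                and r["sign"] != 0
                and row["sign"] != r["sign"]
            )
        )
    combined["sign_change"] = flags
    return combined
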