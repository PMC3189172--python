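"""End-to-end orchestration: load -> summarize -> Gini -> CCA -> inference.

A :class:`RunConfig` fully determines a run (data source, set assignment,
dichotomization rules, permutation count, seed, numerical options), is
round-trippable through YAML, and re-runs to byte-identical numeric outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cca import CanonicalSolution, redundancy, solve_cca, structural_coefficients
from .cohort import CohortTable, DichotomizationRule, read_cohort, summarize, write_cohort
from .gini import AssociationMatrices, gini_correlation_matrix, gini_covariance_matrix
from .inference import InferenceResult, permutation_test, resample_se
from .synthetic import SyntheticSpec, generate, table2_preset

__all__ = ["RunConfig", "RunArtifacts", "run_pipeline", "load_table"]

logger = logging.getLogger("ginicca")

_HIGH_MISSINGNESS_WARN = 30.0  # percent


@dataclass
class RunConfig:
    """Serializable description of one analysis run."""

    output_dir: str
    seed: int = 0
    n_perm: int = 10_000
    n_bootstrap: int = 500
    ridge: float = 0.0
    # either a CSV input ...
    input_csv: str | None = None
    assignment: dict[str, str] | None = None
    missing_token: str = "NA"
    dichotomization_rules: list[dict] = field(default_factory=list)
    # ... or a synthetic cohort (preset margins with overrides)
    synthetic: dict | None = None

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class RunArtifacts:
    table: CohortTable
    summary_path: Path
    assoc: AssociationMatrices
    solution: CanonicalSolution
    inference: InferenceResult
    output_dir: Path


def load_table(config: RunConfig) -> CohortTable:
    if (config.input_csv is None) == (config.synthetic is None):
        raise ValueError("config must set exactly one of input_csv or synthetic")
    if config.synthetic is not None:
        params = dict(config.synthetic)
        params.setdefault("seed", config.seed)
        if params.pop("preset", "table2") != "table2":
            raise ValueError("only the 'table2' synthetic preset is available")
        spec = table2_preset(**params)
        return generate(spec)
    if config.assignment is None:
        raise ValueError("CSV input requires a variable -> set assignment")
    rules = [DichotomizationRule(**r) for r in config.dichotomization_rules]
    return read_cohort(
        config.input_csv, config.assignment, config.missing_token, rules=rules
    )


def run_pipeline(config: RunConfig) -> RunArtifacts:
    """Run the full analysis and write CSV/text artifacts to the output dir.

    Outputs: ``summary.csv`` (descriptive counts), ``covariance.csv`` /
    ``correlation.csv`` / ``pairwise_n.csv`` (association matrices),
    ``loadings.csv`` (per-variable structural coefficients),
    ``redundancy.csv``, ``inference.csv`` (rho, SE, p per variate),
    ``finger_plot.txt`` (top-ranked variables of the first variate),
    ``cohort.csv`` (the analyzed table) and ``manifest.json``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, outdir: Path) -> RunArtifacts:
    table = load_table(config)
    logger.info("stage=load n=%d p=%d q=%d", table.n, table.p, table.q)
    write_cohort(table, outdir / "cohort.csv", config.missing_token)

    summary = summarize(table)
    for _, row in summary.iterrows():
        if row["missing_pct"] > _HIGH_MISSINGNESS_WARN:
            logger.warning(
                "stage=summarize variable=%r missingness %.1f%% exceeds %.0f%%",
                row["variable"], row["missing_pct"], _HIGH_MISSINGNESS_WARN,
            )
    summary_path = outdir / "summary.csv"
    summary.to_csv(summary_path, index=False)

    assoc = gini_correlation_matrix(gini_covariance_matrix(table))
    logger.info(
        "stage=gini min_pairwise_n=%d zero_variance=%s",
        int(assoc.pairwise_n.min()), assoc.zero_variance,
    )
    assoc.matrix_frame("V").to_csv(outdir / "covariance.csv")
    assoc.matrix_frame("R").to_csv(outdir / "correlation.csv")
    assoc.matrix_frame("pairwise_n").to_csv(outdir / "pairwise_n.csv")

    solution = solve_cca(assoc, ridge=config.ridge)
    for entry in solution.repair_log:
        logger.info("stage=cca repair: %s", entry)
    structural_coefficients(assoc, solution).to_csv(outdir / "loadings.csv", index=False)
    redundancy(assoc, solution).to_csv(outdir / "redundancy.csv", index=False)

    inference = permutation_test(
        table, n_perm=config.n_perm, seed=config.seed, ridge=config.ridge
    )
    inference.standard_errors = resample_se(
        table, n_resample=config.n_bootstrap, seed=config.seed + 1, ridge=config.ridge
    )
    inference.se_method = "bootstrap"
    inference.frame().to_csv(outdir / "inference.csv", index=False)
    logger.info(
        "stage=inference rho1=%.4f p1=%.4g n_perm=%d",
        inference.rho[0], inference.p_values[0], inference.n_perm,
    )

    (outdir / "finger_plot.txt").write_text(_finger_plot(solution, inference))
    manifest = {
        "ginicca_version": __version__,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "n_bootstrap": config.n_bootstrap,
        "ridge": config.ridge,
        "n": table.n,
        "p": table.p,
        "q": table.q,
        "n_variates": solution.K,
        "repair_log": solution.repair_log,
        "zero_variance": assoc.zero_variance,
        "min_pairwise_n": int(assoc.pairwise_n.min()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return RunArtifacts(table, summary_path, assoc, solution, inference, outdir)


def _finger_plot(
    solution: CanonicalSolution, inference: InferenceResult, top: int = 8
) -> str:
    """Text ranking of the variables driving the first canonical variate."""
    lines = [
        "First canonical variate",
        f"  rho_1 = {solution.rho[0]:.3f}  "
        f"p = {inference.p_values[0]:.4f} ({inference.n_perm} permutations)",
        "",
    ]
    for label, names, load in (
        ("Exposure/demographic set", solution.x_names, solution.loadings_x[:, 0]),
        ("Symptom/diagnostic set", solution.y_names, solution.loadings_y[:, 0]),
    ):
        lines.append(label)
        order = np.argsort(-np.abs(load))[:top]
        for i in order:
            bar = "#" * max(1, int(round(40 * abs(load[i]))))
            lines.append(f"  {names[i]:<34} {load[i]:+.2f}  {bar}")
        lines.append("")
    return "\n".join(lines)
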