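"""End-to-end pipeline: configuration, orchestration, reporting.

A run loads (or simulates) the participant and outcome tables, validates
them, tunes the matching proportion m by cross-validation for each requested
vision-score variant, compares the tuned and nonpersonalized per-fold MSEs
with a paired Wilcoxon test, evaluates on the held-out validation cohort at
the training-optimal m alongside the global and naive baselines, and writes a
run directory with tuning tables, per-participant model files, figures, a
markdown report, and a log. Every random step derives from the single root
seed, so a run is reproducible from its config and inputs alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import yaml

from .errors import ConfigError, DataError
from .evaluation import (
    DEFAULT_M_GRID,
    TuningResult,
    ValidationReport,
    compare_wilcoxon,
    cross_validate_m,
    holdout_evaluate,
)
from .personalized_model import ModelSpec
from .study_data import (
    load_outcomes,
    load_participants,
    save_outcomes,
    save_participants,
    validate_dataset,
)
from .synthetic_data import study_fixture

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce a full analysis run."""

    participants: str | None = None     # CSV path; None -> synthetic fixture
    outcomes: str | None = None
    variants: tuple[str, ...] = ("smat", "dltv")
    m_grid: tuple[float, ...] = DEFAULT_M_GRID
    k: int = 8
    seed: int = 0
    ridge_fallback: float = 1e-4
    out_dir: str = "runs/matppm"
    verbosity: str = "info"

    def __post_init__(self):
        if (self.participants is None) != (self.outcomes is None):
            raise ConfigError("participants and outcomes paths must be given together")
        if not self.variants:
            raise ConfigError("at least one vision variant is required")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["variants"] = list(self.variants)
        d["m_grid"] = [float(m) for m in self.m_grid]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        d.update({k: v for k, v in overrides.items() if v is not None})
        if "variants" in d:
            d["variants"] = tuple(d["variants"])
        if "m_grid" in d:
            d["m_grid"] = tuple(float(m) for m in d["m_grid"])
        return cls(**d)


@dataclass
class RunResult:
    out_dir: Path
    tuning: dict[str, TuningResult]
    wilcoxon_p: dict[str, float]
    validation: dict[str, ValidationReport]
    summary: dict


def _setup_run_logging(out_dir: Path, verbosity: str) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log", mode="w", encoding="utf-8")
    # no timestamps: run outputs are byte-reproducible under a fixed seed
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("matppm")
    root.setLevel(getattr(logging, verbosity.upper(), logging.INFO))
    root.addHandler(handler)
    return handler


def _plot_tuning(tuning: dict[str, TuningResult], path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for variant, result in tuning.items():
        ax.plot(result.m_grid, result.mean_mse_per_m, marker="o",
                label=f"{variant.upper()}-based")
        ax.axvline(result.optimal_m, linestyle=":", alpha=0.4)
    ax.set_xlabel("matching proportion m")
    ax.set_ylabel("mean CV MSE (success counts)")
    ax.set_title("Cross-validated MSE vs matching proportion")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _render_report(summary: dict) -> str:
    lines = ["# Personalized subtask-success modeling — run report", ""]
    lines.append(f"Seed: {summary['seed']}; folds: {summary['k']}; "
                 f"m grid: {len(summary['m_grid'])} values "
                 f"({summary['m_grid'][0]:.2f}..{summary['m_grid'][-1]:.2f})")
    lines.append(f"Training participants: {summary['n_train']}; "
                 f"validation participants: {summary['n_test']}")
    lines.append("")
    for variant, block in summary["variants"].items():
        lines.append(f"## {variant.upper()}-based model")
        lines.append("")
        lines.append(f"- CV-optimal matching proportion m = {block['optimal_m']:.2f} "
                     f"(mean CV MSE {block['cv_mse_at_optimal']:.4f}; "
                     f"m=1.00 global CV MSE {block['cv_mse_at_global']:.4f})")
        lines.append(f"- Wilcoxon signed-rank, optimal m vs m=1.0 per-fold MSEs: "
                     f"P = {block['wilcoxon_p']:.3f}")
        lines.append(f"- Held-out MSE at m = {block['m_used']:.2f}: "
                     f"personalized {block['personalized_mse']:.4f}, "
                     f"global {block['global_mse']:.4f}, "
                     f"naive {block['naive_mse']:.4f} "
                     f"(naive constant {block['naive_probability']:.4f})")
        lines.append("")
    lines.append("MSE is the mean squared error in predicting the number of "
                 "successful attempts at a subtask; the naive constant is the "
                 "training-set least-squares success probability.")
    lines.append("")
    return "\n".join(lines)


def run_full_analysis(config: RunConfig) -> RunResult:
    """Execute the whole pipeline and write the run directory."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_logging(out_dir, config.verbosity)
    try:
        config.to_yaml(out_dir / "config.yaml")
        if config.participants is None:
            log.info("no input tables configured; simulating the study fixture")
            fixture = study_fixture(seed=config.seed)
            train_profiles, train_outcomes = fixture.train_profiles, fixture.train_outcomes
            test_profiles, test_outcomes = fixture.test_profiles, fixture.test_outcomes
            profiles = fixture.all_profiles
            outcomes = fixture.all_outcomes
        else:
            profiles = load_participants(config.participants)
            outcomes = load_outcomes(config.outcomes)
            train_profiles = [p for p in profiles if p.cohort == "training"]
            test_profiles = [p for p in profiles if p.cohort == "validation"]
            train_ids = {p.participant_id for p in train_profiles}
            train_outcomes = [o for o in outcomes if o.participant_id in train_ids]
            test_outcomes = [o for o in outcomes if o.participant_id not in train_ids]

        report = validate_dataset(profiles, outcomes)
        (out_dir / "validation.txt").write_text(str(report) + "\n", encoding="utf-8")
        if not report.passed:
            raise DataError(f"input validation failed with {len(report.issues)} issues "
                            f"(see {out_dir / 'validation.txt'})")
        if not test_profiles:
            raise DataError("no validation-cohort participants found")

        tuning: dict[str, TuningResult] = {}
        wilcoxon_p: dict[str, float] = {}
        validation: dict[str, ValidationReport] = {}
        summary: dict = {
            "seed": config.seed,
            "k": config.k,
            "m_grid": [float(m) for m in config.m_grid],
            "n_train": len(train_profiles),
            "n_test": len(test_profiles),
            "variants": {},
        }

        for variant in config.variants:
            spec = ModelSpec(vision_variant=variant)
            log.info("tuning %s-based model (k=%d, %d m values)",
                     variant, config.k, len(config.m_grid))
            result = cross_validate_m(
                train_profiles, train_outcomes, spec,
                m_grid=config.m_grid, k=config.k, seed=config.seed,
                fallback_ridge=config.ridge_fallback)
            tuning[variant] = result
            result.to_frame().to_csv(out_dir / f"tuning_{variant}.csv", index=False)

            if result.optimal_m == 1.0:
                p = 1.0    # tuned optimum is the global model itself
            elif any(np.isclose(result.m_grid, 1.0)):
                p = compare_wilcoxon(result.column(result.optimal_m), result.column(1.0))
            else:
                p = float("nan")
            wilcoxon_p[variant] = p

            log.info("holdout evaluation for %s at m=%.2f", variant, result.optimal_m)
            vrep = holdout_evaluate(train_profiles, train_outcomes,
                                    test_profiles, test_outcomes, spec,
                                    m=result.optimal_m,
                                    fallback_ridge=config.ridge_fallback)
            validation[variant] = vrep

            models_dir = out_dir / "models" / variant
            models_dir.mkdir(parents=True, exist_ok=True)
            for pid, coeffs in sorted(vrep.models.items()):
                coeffs.save(models_dir / f"{pid}.txt")
                log.info("personalized fit %s: m=%.2f matched=%d converged=%s penalty=%g",
                         pid, coeffs.m_used, len(coeffs.trained_on),
                         coeffs.converged, coeffs.penalty_used)
            if vrep.global_model is not None:
                vrep.global_model.save(models_dir / "_global.txt")

            grid = np.asarray(result.m_grid)
            summary["variants"][variant] = {
                "optimal_m": result.optimal_m,
                "cv_mse_at_optimal": float(np.nanmin(result.mean_mse_per_m)),
                "cv_mse_at_global": float(result.mean_mse_per_m[
                    int(np.argmin(np.abs(grid - 1.0)))]),
                "wilcoxon_p": p,
                "m_used": vrep.m_used,
                "personalized_mse": vrep.personalized_mse,
                "global_mse": vrep.global_mse,
                "naive_mse": vrep.naive_mse,
                "naive_probability": vrep.naive_probability,
                "n_test_rows": vrep.n_test_rows,
            }

        figures = out_dir / "figures"
        figures.mkdir(exist_ok=True)
        _plot_tuning(tuning, figures / "mse_vs_m.png")

        (out_dir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True), encoding="utf-8")
        (out_dir / "report.md").write_text(_render_report(summary), encoding="utf-8")
        log.info("run complete")
        return RunResult(out_dir=out_dir, tuning=tuning, wilcoxon_p=wilcoxon_p,
                         validation=validation, summary=summary)
    finally:
        logging.getLogger("matppm").removeHandler(handler)
        handler.close()


def simulate_to_dir(seed: int, out_dir: str | Path) -> Path:
    """Write a synthetic study-shaped dataset (CSV tables + truth) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fixture = study_fixture(seed=seed)
    save_participants(fixture.all_profiles, out / "participants.csv")
    save_outcomes(fixture.all_outcomes, out / "outcomes.csv")
    fixture.truth.save(out / "truth.json")
    return out
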