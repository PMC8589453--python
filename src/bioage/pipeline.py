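"""End-to-end orchestration: exclusions -> split -> preprocessing fit on
training controls -> screening -> model calibration -> out-of-sample BA for
held-out controls and disease groups -> dAge / age-ratio metrics and group
comparisons -> optional survival stage.

Every run writes its result tables as CSV plus a manifest (seeds, panel,
package version, input checksums) so it can be reproduced from the echoed
configuration alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import BioAgeError, PipelineError
from .io import read_cohort, write_cohort
from .metrics import compare_groups, compute_metrics, correlate_with_ratio
from .models import fit_kdm, fit_mlr, predict_kdm, predict_mlr
from .panels import get_panel
from .prep import apply_exclusions, train_test_split
from .preprocess import Preprocessor
from .screening import redundancy_check, univariate_screen
from .survival import fit_cox

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one analysis run.

    Either ``input_path`` (CSV/TSV/SAS-XPORT cohort) or ``cohort`` (an
    in-memory table) must be provided.  ``estimators`` may include
    ``"kdm1"`` and ``"mlr"``; the Phenotypic Age estimator has its own
    fixed coefficients and is run directly via :func:`bioage.phage.compute_phage`.
    """

    input_path: str | None = None
    input_format: str | None = None
    column_map: dict[str, str] = field(default_factory=dict)
    cohort: pd.DataFrame | None = None

    panel_id: str = "kdm8"
    biomarkers: tuple[str, ...] | None = None  # overrides the built-in panel
    estimators: tuple[str, ...] = ("kdm1", "mlr")

    a1c_cutoff: float | None = 5.7
    age_bounds: tuple[float, float] = (20.0, 80.0)
    train_fraction: float = 2.0 / 3.0
    winsor_limits: tuple[float, float] = (1.0, 99.0)
    use_box_cox: bool = True
    p_threshold: float = 0.05
    control_label: str = "control"
    seed: int = 0

    survival: bool = False  # requires time/event columns on disease rows
    survival_covariates: tuple[str, ...] = ()

    output_dir: str | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a YAML or JSON run configuration."""
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            obj = yaml.safe_load(text)
        else:
            obj = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise PipelineError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("age_bounds", "winsor_limits", "estimators", "biomarkers",
                    "survival_covariates"):
            if key in obj and obj[key] is not None:
                obj[key] = tuple(obj[key])
        return cls(**obj)


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the result bundle as a dict.

    Bundle keys: ``cohort, exclusion_log, screen, redundancy, models,
    ba_table, metrics, comparisons, ratio_correlations, cox, manifest``.
    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    bundle: dict = {}
    stage = "load"
    try:
        if config.cohort is not None:
            cohort = config.cohort.copy()
            read_log = None
        elif config.input_path:
            cohort, read_log = read_cohort(
                config.input_path, config.input_format, config.column_map or None
            )
        else:
            raise PipelineError("config must provide 'input_path' or 'cohort'")
        panel = get_panel(config.panel_id, config.biomarkers)
        panel.validate_against(cohort)
        markers = list(panel.biomarkers)

        stage = "exclusions"
        a1c_col = "a1c" if "a1c" in cohort.columns else None
        cutoff = config.a1c_cutoff if a1c_col else None
        cohort, excl_log = apply_exclusions(
            cohort,
            a1c_cutoff=cutoff,
            age_bounds=config.age_bounds,
            required_columns=markers + ["ca", "gender"],
            control_label=config.control_label,
        )
        bundle["cohort"] = cohort
        bundle["exclusion_log"] = excl_log

        stage = "split"
        is_control = cohort["group"].eq(config.control_label) if "group" in cohort else pd.Series(True, index=cohort.index)
        controls = cohort.loc[is_control]
        others = cohort.loc[~is_control]
        train, test = train_test_split(controls, config.train_fraction, config.seed)

        stage = "preprocess"
        prep = Preprocessor(
            markers,
            winsor_limits=config.winsor_limits,
            use_box_cox=config.use_box_cox,
        ).fit(train)
        train_t = prep.transform(train)
        test_t = prep.transform(test)
        others_t = prep.transform(others) if len(others) else others

        stage = "screen"
        screen = univariate_screen(train_t, markers, p_threshold=config.p_threshold)
        screen.redundancy_drops = redundancy_check(train_t, markers)
        bundle["screen"] = screen
        bundle["redundancy"] = screen.redundancy_drops

        stage = "fit"
        models: dict[str, object] = {}
        if "kdm1" in config.estimators:
            models["kdm1"] = fit_kdm(train_t, markers, panel_id=panel.panel_id)
        if "mlr" in config.estimators:
            models["mlr"] = fit_mlr(train_t, markers, panel_id=panel.panel_id)
        bundle["models"] = models

        stage = "predict"
        scored = pd.concat([test_t, others_t]) if len(others) else test_t
        ba_tables = []
        for name, model in models.items():
            if name == "kdm1":
                ba_tables.append(predict_kdm(model, scored))
            else:
                ba_tables.append(predict_mlr(model, scored))
        ba_table = pd.concat(ba_tables, ignore_index=True)
        bundle["ba_table"] = ba_table

        stage = "metrics"
        metrics = compute_metrics(ba_table, cohort)
        bundle["metrics"] = metrics

        comparisons = []
        if "group" in cohort.columns:
            for est in metrics["estimator"].unique():
                m = metrics.loc[metrics["estimator"] == est]
                ctrl = m.loc[m["group"] == config.control_label]
                for grp in sorted(set(m["group"]) - {config.control_label}):
                    comparisons.append(
                        (est, compare_groups(m.loc[m["group"] == grp], ctrl))
                    )
        bundle["comparisons"] = comparisons
        if len(others):
            first_est = next(iter(models))
            m = metrics.loc[
                (metrics["estimator"] == first_est)
                & (metrics["group"] != config.control_label)
            ]
            bundle["ratio_correlations"] = correlate_with_ratio(m, cohort, markers)
        else:
            bundle["ratio_correlations"] = []

        if config.survival:
            stage = "survival"
            first_est = next(iter(models))
            m = metrics.loc[metrics["estimator"] == first_est]
            surv = m.merge(
                cohort[["subject_id", "time", "event", *config.survival_covariates]],
                on="subject_id",
            )
            bundle["cox"] = {
                "continuous": fit_cox(
                    surv, "continuous", config.survival_covariates
                ),
                "dichotomized": fit_cox(
                    surv, "dichotomized-at-median", config.survival_covariates
                ),
            }

        stage = "write"
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "panel_id": panel.panel_id,
            "biomarkers": markers,
            "estimators": list(config.estimators),
            "train_fraction": config.train_fraction,
            "a1c_cutoff": config.a1c_cutoff,
            "age_bounds": list(config.age_bounds),
            "exclusions": excl_log.as_dict(),
            "n_train": len(train),
            "n_test": len(test),
            "n_other": len(others),
            "inputs": (
                {config.input_path: _checksum(config.input_path)}
                if config.input_path
                else {}
            ),
        }
        bundle["manifest"] = manifest
        if config.output_dir:
            out = Path(config.output_dir)
            out.mkdir(parents=True, exist_ok=True)
            write_cohort(ba_table, out / "ba_table.csv")
            write_cohort(metrics, out / "metrics.csv")
            write_cohort(screen.table, out / "screen_report.csv")
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            cfg = dataclasses.asdict(config)
            cfg.pop("cohort", None)
            (out / "run_config.json").write_text(json.dumps(cfg, indent=2, default=str))
    except PipelineError:
        raise
    except BioAgeError as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return bundle
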