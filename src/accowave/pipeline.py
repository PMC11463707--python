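"""End-to-end workflow: simulate -> preprocess -> PCA -> fit -> generate -> validate.

A single config carries every constant of the published workflow shape
(6 demands, 25 modes, 99.97% variance cutoff, 2 Gaussian components,
1000 generated wavefronts) so the default invocation reproduces it;
every constant is overridable.  Reruns with the same config and seed are
bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from accowave.io import cohort_to_table, read_cohort_csv, write_cohort_csv
from accowave.mixture import fit_em, generate_cohort
from accowave.pca import DEFAULT_CUTOFF, cumulative_variance_table, fit_basis, project
from accowave.population import PopulationSpec, generate_population
from accowave.preprocess import CohortConfig, preprocess_cohort
from accowave.validation import validate_cohorts


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end run."""

    seed: int = 0
    simulate: bool = True  # draw the input cohort instead of reading a CSV
    n_subjects: int = 191
    input_csv: str | None = None
    cutoff: float = DEFAULT_CUTOFF
    n_generate: int = 1000
    em_tol: float = 1e-8
    em_max_iter: int = 500
    em_restarts: int = 5
    em_ridge_scale: float = 1e-6
    alpha: float = 0.05
    tost_margin_sd_fraction: float = 0.2
    output_dir: str = "accowave_run"
    cohort: CohortConfig = field(default_factory=CohortConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        cohort = payload.pop("cohort", None)
        cfg = cls(**payload)
        if cohort:
            pupils = cohort.get("standard_pupils")
            if pupils is not None:
                cohort["standard_pupils"] = {int(k): float(v) for k, v in pupils.items()}
            cfg.cohort = CohortConfig(**cohort)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def run_pipeline(config: PipelineConfig | None = None) -> dict:
    """Execute every stage and write the artifacts.

    Returns a dict with the in-memory artifacts (raw table, cohort
    matrix, basis, model, synthetic cohort, validation reports) plus the
    audit log.  Artifacts are also serialized under ``config.output_dir``.
    """
    config = config or PipelineConfig()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed}

    try:
        if config.simulate:
            raw = generate_population(
                PopulationSpec(n_subjects=config.n_subjects, seed=config.seed)
            )
        else:
            if not config.input_csv:
                raise ValueError("input_csv required when simulate is false")
            raw = read_cohort_csv(config.input_csv)
    except Exception as e:
        raise RuntimeError(f"[input] {e}") from e
    write_cohort_csv(raw, out / "cohort_raw.csv")

    try:
        cohort, exclusion_log = preprocess_cohort(raw, config.cohort)
    except Exception as e:
        raise RuntimeError(f"[preprocess] {e}") from e
    log["n_subjects_kept"] = len(cohort.subject_ids)
    log["n_cells_imputed"] = int(cohort.imputed.sum())
    (out / "exclusion_log.json").write_text(json.dumps(exclusion_log, indent=1))

    try:
        basis = fit_basis(cohort.data, config.cutoff)
    except Exception as e:
        raise RuntimeError(f"[pca] {e}") from e
    log["k_retained"] = basis.k
    log["variance_retained"] = float(basis.cumulative_variance[-1])
    basis.to_json(out / "eigenbasis.json")
    cumulative_variance_table(basis, cohort.data).to_csv(
        out / "cumulative_variance.csv", index=False, float_format="%.17g"
    )

    scores = project(cohort.data, basis)
    try:
        model = fit_em(
            scores,
            seed=config.seed,
            tol=config.em_tol,
            max_iter=config.em_max_iter,
            restarts=config.em_restarts,
            ridge_scale=config.em_ridge_scale,
        )
    except Exception as e:
        raise RuntimeError(f"[fit] {e}") from e
    log["em_final_loglik"] = float(model.log_likelihood_trace[-1])
    log["em_weights"] = model.weights.tolist()
    model.to_json(out / "bigaussian_model.json")

    try:
        synthetic = generate_cohort(
            basis, model, config.n_generate, seed=config.seed,
            standard_pupils=config.cohort.standard_pupils,
        )
    except Exception as e:
        raise RuntimeError(f"[generate] {e}") from e
    write_cohort_csv(cohort_to_table(synthetic), out / "cohort_synthetic.csv")

    try:
        report_ev, report_z = validate_cohorts(
            cohort.data,
            synthetic.data,
            basis,
            alpha=config.alpha,
            margin_sd_fraction=config.tost_margin_sd_fraction,
            original_mask=cohort.imputed,
        )
    except Exception as e:
        raise RuntimeError(f"[validate] {e}") from e
    for rep, name in [(report_ev, "eigenvectors"), (report_z, "zernike")]:
        rep.table.to_csv(out / f"validation_{name}.csv", index=False, float_format="%.17g")
        log[f"bonferroni_m_{name}"] = rep.m
        log[f"pass_both_{name}"] = rep.n_pass_both
    (out / "run_log.json").write_text(json.dumps(log, indent=1))

    return {
        "raw": raw,
        "cohort": cohort,
        "exclusion_log": exclusion_log,
        "basis": basis,
        "model": model,
        "synthetic": synthetic,
        "report_eigenvectors": report_ev,
        "report_zernike": report_z,
        "log": log,
    }
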