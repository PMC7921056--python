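"""End-to-end orchestration of the four-step weighted causal LC-2PL analysis.

Stage 1 fits the sequential treatment models, stage 2 computes and trims
the inverse-probability weights, stage 3 selects and fits the weighted
latent-class 2PL measurement model per outcome set, stage 4 adds the
adjacent-logit structural model.  Every run emits CSV tables plus a JSON
manifest recording the config hash, seeds, timings and output paths; runs
are pure functions of (cohort, design, options, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .lc2pl import (
    measurement_table,
    outcome_matrix,
    select_k,
)
from .propensity import (
    DEFAULT_PROB_FLOOR,
    DEFAULT_TRIM_QUANTILES,
    balance_diagnostics,
    compute_weights,
    fit_block_models,
    trim_weights,
)
from .structural import atet_table, fit_structural, predictor_matrix
from .study_data import PatientRecord, StudyDesign, summarize_cohort

logger = logging.getLogger("causallc")


@dataclass
class PipelineOptions:
    out_dir: str | Path = "causallc_out"
    seed: int = 0
    k_range: tuple[int, ...] = (1, 2, 3, 4, 5)
    trim_quantiles: tuple[float, float] = DEFAULT_TRIM_QUANTILES
    weight_mode: str = "sum"
    prob_floor: float = DEFAULT_PROB_FLOOR
    structural_mode: str = "joint"
    star_mode: str = "table"
    n_starts: int = 20
    outcome_sets: tuple[str, ...] | None = None   # default: all declared


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    timings: dict[str, float] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    selected_k: dict[str, int] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _hash_config(design: StudyDesign, options: PipelineOptions) -> str:
    payload = repr(design) + repr(asdict(options))
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(
    records: Sequence[PatientRecord],
    design: StudyDesign,
    options: PipelineOptions | None = None,
) -> RunManifest:
    """Execute stages 1-4 for every declared outcome set; return the manifest."""
    options = options or PipelineOptions()
    out = Path(options.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=_hash_config(design, options),
        seed=options.seed,
        version=__version__,
    )

    def emit(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False)
        manifest.outputs.append(str(path))

    stage = "summary"
    try:
        t0 = time.perf_counter()
        emit(summarize_cohort(records, design), "cohort_summary.csv")
        manifest.timings[stage] = time.perf_counter() - t0

        stage = "treatment_models"
        t0 = time.perf_counter()
        fits = fit_block_models(records, design)
        coef_rows = []
        for f in fits:
            coef_rows.append(
                {"treatment": f.treatment, "block": f.block, "kind": f.kind,
                 "term": "<intercept>", "coef": f.intercept}
            )
            coef_rows += [
                {"treatment": f.treatment, "block": f.block, "kind": f.kind,
                 "term": pred, "coef": c}
                for pred, c in zip(f.predictors, f.coef)
            ]
        emit(pd.DataFrame(coef_rows), "treatment_models.csv")
        manifest.timings[stage] = time.perf_counter() - t0

        stage = "weights"
        t0 = time.perf_counter()
        weights = compute_weights(
            fits, records, design, mode=options.weight_mode,
            floor=options.prob_floor,
        )
        weights = trim_weights(weights, *options.trim_quantiles)
        emit(weights.to_frame(), "weights.csv")
        emit(balance_diagnostics(records, weights, design), "balance.csv")
        manifest.timings[stage] = time.perf_counter() - t0

        set_names = options.outcome_sets or tuple(design.outcome_sets)
        for s_idx, set_name in enumerate(set_names):
            stage = f"measurement[{set_name}]"
            t0 = time.perf_counter()
            Y, dim_index = outcome_matrix(records, set_name, design)
            items = design.outcome_sets[set_name].items
            fit, bic_table = select_k(
                Y, weights.normalized, list(options.k_range), dim_index,
                seed=options.seed + 1000 * (s_idx + 1),
                n_starts=options.n_starts,
            )
            manifest.selected_k[set_name] = fit.params.k
            emit(bic_table, f"bic_{set_name}.csv")
            emit(measurement_table(fit, items), f"measurement_{set_name}.csv")
            emit(
                pd.DataFrame(
                    fit.posterior,
                    columns=[f"class_{u + 1}" for u in range(fit.params.k)],
                ).assign(map_class=fit.map_classes),
                f"posterior_{set_name}.csv",
            )
            manifest.timings[stage] = time.perf_counter() - t0

            stage = f"structural[{set_name}]"
            t0 = time.perf_counter()
            Dmat, pred_names = predictor_matrix(records, design)
            if fit.params.k > 1:
                sp = fit_structural(
                    Y, weights.normalized, fit, Dmat, pred_names,
                    mode=options.structural_mode,
                )
                for u in range(2, sp.k + 1):
                    emit(
                        atet_table(sp, (u - 1, u), star_mode=options.star_mode),
                        f"structural_{set_name}_class{u - 1}_vs_{u}.csv",
                    )
                summary = {
                    "outcome_set": set_name, "k": sp.k, "loglik": sp.loglik,
                    "converged": bool(sp.converged), "mode": sp.mode,
                }
            else:
                logger.warning(
                    "one latent class selected for %r; no structural model",
                    set_name,
                )
                summary = {"outcome_set": set_name, "k": 1}
            path = out / f"fit_summary_{set_name}.json"
            with open(path, "w") as fh:
                json.dump(
                    {
                        **summary,
                        "measurement_loglik": fit.loglik,
                        "bic": fit.bic,
                        "n_par": fit.n_par,
                        "em_iterations": fit.n_iter,
                        "em_converged": bool(fit.converged),
                        "seed": options.seed,
                    },
                    fh, indent=2,
                )
            manifest.outputs.append(str(path))
            manifest.timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        manifest.save(out / "manifest_partial.json")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest.save(manifest_path)
    manifest.outputs.append(str(manifest_path))
    missing = [p for p in manifest.outputs if not Path(p).exists()]
    if missing:
        raise RuntimeError(f"manifest lists missing outputs: {missing}")
    return manifest
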