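"""End-to-end reproducible runs: simulate → window → features → select → model.

A run is described by a :class:`RunConfig` (JSON-serializable); its outputs
are plain CSV/JSON files in the run directory plus a ``run.log`` recording
package versions, the seed, and the row counts entering and leaving every
stage so survey attrition is auditable.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .config import SimulationConfig
from .dataset import StudyDataset
from .features import build_feature_table
from .glmm import GlmmFit
from .selection import OUTCOMES, forward_build, select_features, \
    select_window, sweep_windows
from .simulate import simulate_study

DEFAULT_LENGTHS = [float(l) for l in range(3, 31, 3)]


class PipelineError(RuntimeError):
    pass


class RunConfig(BaseModel):
    """One pipeline run: either simulate a study or read the three CSVs."""

    simulate: SimulationConfig | None = Field(default_factory=SimulationConfig)
    input_dir: str | None = None        # directory with sensors/locations/surveys.csv
    buffer_min: float = 12.0
    lengths: list[float] = Field(default_factory=lambda: list(DEFAULT_LENGTHS))
    alpha: float = 0.05
    n_quad: int = 25
    seed: int | None = None             # overrides simulate.seed when set
    out_dir: str = "wardtrig_run"

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def _fit_record(fit: GlmmFit) -> dict:
    ci = fit.conf_int
    return {
        "terms": fit.terms,
        "beta": [float(b) for b in fit.beta],
        "se": [float(s) for s in fit.se],
        "p": [float(p) for p in fit.pvalues],
        "ci": [[float(a), float(b)] for a, b in ci],
        "sigma_b": fit.sigma_b,
        "loglik": fit.loglik,
        "deviance": fit.deviance,
        "n_obs": fit.n_obs,
        "n_groups": fit.n_groups,
        "n_quad": fit.n_quad,
        "converged": fit.converged,
    }


def load_dataset(cfg: RunConfig) -> StudyDataset:
    if cfg.input_dir is not None:
        return StudyDataset.read_csvs(cfg.input_dir)
    sim = cfg.simulate or SimulationConfig()
    if cfg.seed is not None:
        sim = sim.model_copy(update={"seed": cfg.seed})
    return simulate_study(sim)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full analysis; returns the run directory.

    Partial outputs are removed if any stage fails, so a run directory is
    either complete or absent.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log: list[str] = [
        f"wardtrig {__version__} | python {sys.version.split()[0]} | "
        f"numpy {np.__version__} | pandas {pd.__version__}",
        f"seed: {cfg.seed if cfg.seed is not None else (cfg.simulate.seed if cfg.simulate else 'n/a')}",
        f"lengths: {cfg.lengths}  buffer: {cfg.buffer_min} min  "
        f"alpha: {cfg.alpha}",
    ]

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        written.append(path)
        return path

    try:
        ds = load_dataset(cfg)
        log.append(f"surveys scheduled: {len(ds.surveys)} across "
                   f"{ds.surveys['patient_id'].nunique()} patients")
        log.extend(ds.log)

        feats, flog, std = build_feature_table(ds, cfg.lengths,
                                               buffer_min=cfg.buffer_min)
        log.extend(flog)
        emit("features.csv", lambda p: feats.to_csv(p, index=False))
        qcols = ["survey_id", "length", "passed", "failed_criteria"]
        emit("quality_report.csv",
             lambda p: feats[qcols].to_csv(p, index=False))
        emit("standardizer.json", lambda p: p.write_text(json.dumps(
            {str(k): v for k, v in std.items()}, indent=1, default=list)))

        n_pass = int(feats[feats["length"] == cfg.lengths[0]]["passed"].sum())
        if n_pass == 0:
            raise PipelineError(
                "0 rows remain after the quality stage; nothing to model")

        grid = sweep_windows(feats, n_quad=cfg.n_quad)
        emit("beta_grid.csv", lambda p: grid.to_csv(p, index=False))
        if len(cfg.lengths) == 1:
            length = float(cfg.lengths[0])
            log.append(f"single length supplied; window sweep skipped, "
                       f"using {length:g} min")
        else:
            length = select_window(grid, alpha=cfg.alpha)
            log.append(f"selected window length: {length:g} min")
        sel = select_features(grid, length, alpha=cfg.alpha)
        emit("selection.json",
             lambda p: p.write_text(json.dumps(sel.to_dict(), indent=1)))
        log.append(f"dropped modalities: {sel.dropped_modalities or 'none'}")

        at = feats[feats["length"] == length]
        fits_doc: dict[str, dict] = {}
        anova_rows = []
        summary_rows = []
        for outcome in OUTCOMES:
            br = forward_build(at, sel, outcome, alpha=cfg.alpha,
                               n_quad=cfg.n_quad)
            log.append(f"build-up {outcome}: n={br.n_obs}, kept terms: "
                       f"{br.kept_terms}")
            log.extend(br.log)
            fits_doc[outcome] = {str(m): _fit_record(f)
                                 for m, f in br.fits.items()}
            a = br.anova.assign(outcome=outcome)
            anova_rows.append(a)
        anova = pd.concat(anova_rows, ignore_index=True)
        emit("fits.json",
             lambda p: p.write_text(json.dumps(fits_doc, indent=1)))
        emit("anova.csv", lambda p: anova.to_csv(p, index=False))

        # Fig-F4-style summary: β per feature × modality × outcome at the
        # chosen window, with significance markers and selection flags
        gsel = grid[grid["length"] == length]
        for row in gsel.itertuples():
            chosen = sel.chosen.get((row.outcome, row.modality), {})
            summary_rows.append({
                "outcome": row.outcome, "modality": row.modality,
                "feature": row.feature, "beta": row.beta, "p": row.p,
                "significant": bool(row.converged and row.p < cfg.alpha),
                "selected": chosen.get("feature") == row.feature,
            })
        emit("summary_table.csv", lambda p: pd.DataFrame(summary_rows)
             .to_csv(p, index=False))
        emit("run.log", lambda p: p.write_text("\n".join(log) + "\n"))
        return out
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
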