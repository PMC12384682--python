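"""Exploratory window/feature selection and the forward model build-up.

Stage 1 (exploratory): for every window length, modality, descriptive
feature and outcome, fit the single-predictor model

    outcome ~ z_feature + time_group + (1 | patient)

and collect the β grid.  The analysis window is the length where the most
cells are simultaneously significant and at their across-length maximum
|β|; per (outcome, modality) the most informative feature is the one with
the largest |β| at that length, and a modality with no significant feature
for any outcome is dropped altogether (the fate of temperature in this
design).

Stage 2 (build-up): per outcome, models 0–9 grow from a patient-intercept-
only model: + time group, + majority-room group, + sound feature, + light
feature, + both, then sound×time / sound×room / light×time / light×room
interactions.  Each addition is gated by a chi-square ANOVA comparison;
the contextual covariates are retained regardless of their test (domain
knowledge: sundowning and location confounding), environmental and
interaction terms only on a significant improvement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import MODALITIES
from .features import FEATURE_NAMES
from .glmm import GlmmFit, LrtResult, ModelSpec, SeparationError, fit_glmm, \
    fit_model, lrt

OUTCOMES = ("agitation", "motor", "verbal")


# ---------------------------------------------------------------------------
# stage 1: the β grid


def sweep_windows(
    features: pd.DataFrame,
    outcomes: tuple[str, ...] = OUTCOMES,
    modalities: tuple[str, ...] = MODALITIES,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
    n_quad: int = 25,
) -> pd.DataFrame:
    """Fit every single-predictor exploratory model in the feature table.

    ``features`` holds one row per survey × length (from
    :func:`wardtrig.features.build_feature_table`).  Returns the β grid:
    one row per (length, modality, feature, outcome) with β̂, SE, Wald p
    and a convergence flag; non-converged cells carry NaN estimates and
    are never silently imputed.
    """
    rows = []
    for length, sub in features.groupby("length", sort=True):
        for outcome in outcomes:
            for modality in modalities:
                for feat in feature_names:
                    zcol = f"z_{modality}_{feat}"
                    rec = {"length": length, "modality": modality,
                           "feature": feat, "outcome": outcome,
                           "beta": np.nan, "se": np.nan, "p": np.nan,
                           "converged": False}
                    try:
                        fit = fit_model(
                            sub, ModelSpec(outcome, (zcol, "time_group")),
                            n_quad=n_quad)
                        if fit.converged:
                            est = fit[zcol]
                            rec.update(beta=est["beta"], se=est["se"],
                                       p=est["p"], converged=True)
                    except (SeparationError, ValueError):
                        pass
                    rows.append(rec)
    return pd.DataFrame(rows)


def select_window(grid: pd.DataFrame, alpha: float = 0.05,
                  default_length: float = 21.0) -> float:
    """Window length with the maximum amount of information.

    Score per length = number of (outcome, modality, feature) cells that
    are significant at ``alpha`` *and* attain their across-length maximum
    |β̂| at that length; ties break to the longer window (more context).
    Requires ≥ 80% converged cells per length.
    """
    conv = grid.groupby("length")["converged"].mean()
    bad = conv[conv < 0.8]
    if len(bad):
        raise ValueError(
            f"grid too incomplete at lengths {list(bad.index)}: "
            f"{bad.to_dict()}")
    scores: dict[float, int] = {float(l): 0 for l in conv.index}
    for _, cell in grid[grid["converged"]].groupby(
            ["outcome", "modality", "feature"]):
        best = cell.loc[cell["beta"].abs().idxmax()]
        if best["p"] < alpha:
            scores[float(best["length"])] += 1
    if not any(scores.values()):
        import warnings
        warnings.warn("no significant maxima in grid; falling back to the "
                      f"configured default length {default_length}")
        return default_length
    return max(scores, key=lambda l: (scores[l], l))


@dataclass
class SelectionResult:
    length: float
    #: (outcome, modality) -> {"feature", "beta", "p"}
    chosen: dict[tuple[str, str], dict] = field(default_factory=dict)
    dropped_modalities: list[str] = field(default_factory=list)

    def feature_col(self, outcome: str, modality: str) -> str | None:
        if modality in self.dropped_modalities:
            return None
        c = self.chosen.get((outcome, modality))
        return None if c is None else f"z_{modality}_{c['feature']}"

    def to_dict(self) -> dict:
        return {
            "length": self.length,
            "chosen": {f"{o}/{m}": v for (o, m), v in self.chosen.items()},
            "dropped_modalities": self.dropped_modalities,
        }


def select_features(grid: pd.DataFrame, length: float,
                    alpha: float = 0.05) -> SelectionResult:
    """Most informative feature per (outcome, modality) at one length.

    Largest |β̂| wins; exact ties break by the fixed feature order
    (min, max, mean, median, sd).  A modality is dropped from the build-up
    for all outcomes iff it has no significant feature for any outcome at
    this length.
    """
    at = grid[(grid["length"] == length) & grid["converged"]]
    if at.empty:
        raise ValueError(f"grid has no converged cells at length {length}")
    order = {f: i for i, f in enumerate(FEATURE_NAMES)}
    result = SelectionResult(length=length)
    for (outcome, modality), cell in at.groupby(["outcome", "modality"]):
        cell = cell.assign(_rank=cell["feature"].map(order))
        cell = cell.sort_values(["_rank"]).reset_index()
        best = cell.loc[cell["beta"].abs().round(12).idxmax()]
        result.chosen[(outcome, modality)] = {
            "feature": str(best["feature"]), "beta": float(best["beta"]),
            "p": float(best["p"]),
        }
    for modality in at["modality"].unique():
        cell = at[at["modality"] == modality]
        if not (cell["p"] < alpha).any():
            result.dropped_modalities.append(str(modality))
    return result


# ---------------------------------------------------------------------------
# stage 2: forward build-up (models 0–9)

#: ANOVA comparisons of the build-up, (model, nested-in) pairs
BUILDUP_COMPARISONS = (
    (1, 0), (2, 1), (3, 2), (4, 2), (5, 2), (5, 3), (5, 4),
    (6, 3), (7, 3), (8, 4), (9, 4),
)


def buildup_specs(outcome: str, sound_col: str | None,
                  light_col: str | None) -> dict[int, ModelSpec]:
    """Model structures 0–9 for one outcome.

    Models involving a dropped modality are omitted (with both dropped the
    build-up stops at the contextual model 2).
    """
    ctx = ("time_group", "maj_room_group")
    specs = {
        0: ModelSpec(outcome, ()),
        1: ModelSpec(outcome, ("time_group",)),
        2: ModelSpec(outcome, ctx),
    }
    if sound_col:
        specs[3] = ModelSpec(outcome, ctx + (sound_col,))
        specs[6] = ModelSpec(outcome, ctx + (sound_col,
                                             f"{sound_col}:time_group"))
        specs[7] = ModelSpec(outcome, ctx + (sound_col,
                                             f"{sound_col}:maj_room_group"))
    if light_col:
        specs[4] = ModelSpec(outcome, ctx + (light_col,))
        specs[8] = ModelSpec(outcome, ctx + (light_col,
                                             f"{light_col}:time_group"))
        specs[9] = ModelSpec(outcome, ctx + (light_col,
                                             f"{light_col}:maj_room_group"))
    if sound_col and light_col:
        specs[5] = ModelSpec(outcome, ctx + (sound_col, light_col))
    return specs


@dataclass
class BuildResult:
    outcome: str
    fits: dict[int, GlmmFit]
    anova: pd.DataFrame       # model, vs, variable_added, delta_dev, df, p, keep
    kept_terms: list[str]
    n_obs: int
    log: list[str] = field(default_factory=list)


def forward_build(
    features_at_length: pd.DataFrame, selection: SelectionResult,
    outcome: str, alpha: float = 0.05, n_quad: int = 25,
) -> BuildResult:
    """Run the model 0–9 build-up with ANOVA gating for one outcome.

    All models are fitted on the same rows (listwise deletion over the
    union of covariates), so every ANOVA comparison is valid.  Context
    terms are always retained; the sound/light terms and their
    interactions only on a significant likelihood-ratio improvement.
    A non-converged fit aborts its branch; the remaining branches and
    comparisons still run.
    """
    sound_col = selection.feature_col(outcome, "sound")
    light_col = selection.feature_col(outcome, "light")
    specs = buildup_specs(outcome, sound_col, light_col)
    df = features_at_length
    if "passed" in df.columns:
        df = df[df["passed"]]
    need = [c for c in (sound_col, light_col) if c]
    df = df.dropna(subset=need)

    log: list[str] = []
    fits: dict[int, GlmmFit] = {}
    for mid in sorted(specs):
        spec = specs[mid]
        # warm-start from the largest already-fitted nested model: the
        # design columns of a nested spec are a prefix of the fuller one
        start = None
        nested_ids = [i for i in fits
                      if fits[i].spec.is_nested_in(spec) and fits[i].converged]
        if nested_ids:
            base = fits[max(nested_ids, key=lambda i: fits[i].df_fixed)]
            pad = np.zeros(0)
            start = np.concatenate([
                base.beta, pad,
                [np.log(base.sigma_b) if base.sigma_b > 1e-3 else 0.0]])
        try:
            fit = _fit_padded(df, spec, n_quad, start)
        except (SeparationError, ValueError) as e:
            log.append(f"model {mid} ({outcome}): not fitted — {e}")
            continue
        if not fit.converged:
            log.append(f"model {mid} ({outcome}): non-convergence — "
                       f"{fit.message}; branch aborted")
            continue
        fits[mid] = fit

    rows = []
    results: dict[tuple[int, int], LrtResult] = {}
    for mid, vs in BUILDUP_COMPARISONS:
        if mid not in fits or vs not in fits:
            continue
        res = lrt(fits[vs], fits[mid], alpha=alpha)
        results[(mid, vs)] = res
        added = sorted(set(fits[mid].spec.terms) - set(fits[vs].spec.terms))
        rows.append({"model": mid, "vs": vs,
                     "variable_added": "+".join(added),
                     "delta_deviance": res.delta_deviance,
                     "df": res.delta_df, "p": res.pvalue, "keep": res.keep})
    anova = pd.DataFrame(rows)

    def _keep(*pairs) -> bool:
        return any(results[p].keep for p in pairs if p in results)

    kept = ["time_group", "maj_room_group"]       # domain-knowledge override
    sound_kept = sound_col and _keep((3, 2), (5, 4))
    light_kept = light_col and _keep((4, 2), (5, 3))
    if sound_kept:
        kept.append(sound_col)
        if _keep((6, 3)):
            kept.append(f"{sound_col}:time_group")
        if _keep((7, 3)):
            kept.append(f"{sound_col}:maj_room_group")
    if light_kept:
        kept.append(light_col)
        if _keep((8, 4)):
            kept.append(f"{light_col}:time_group")
        if _keep((9, 4)):
            kept.append(f"{light_col}:maj_room_group")
    return BuildResult(outcome=outcome, fits=fits, anova=anova,
                       kept_terms=kept, n_obs=len(df), log=log)


def _fit_padded(df, spec: ModelSpec, n_quad: int, start):
    """fit_model with a warm start padded to the spec's design width."""
    from .glmm import build_design
    sub = df.dropna(subset=[c for c in spec.columns
                            if c in df.columns and c not in
                            ("time_group", "maj_room_group")])
    y, X, names, groups = build_design(sub, spec)
    if start is not None:
        p = X.shape[1]
        beta0 = np.zeros(p)
        k = min(len(start) - 1, p)
        beta0[:k] = start[:k]
        start = np.concatenate([beta0, [start[-1]]])
    return fit_glmm(y, X, groups, term_names=names, spec=spec, n_quad=n_quad,
                    start=start, row_index=sub.index.to_numpy())
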