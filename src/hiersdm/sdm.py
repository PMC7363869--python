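"""Presence / pseudo-absence ensemble modelling for one species and tier.

The modelling recipe, per species and spatial tier:

* draw several sets of random pseudo-absences from the valid region
  (presence cells excluded), each optionally carrying per-point weights —
  at the regional tier the weights come from the inverse-logistic transform
  of the global climate model's projected suitability
  (``weight = 1 / (1 + (p/(p-1))^2)``, 0 at p = 1), so pseudo-absences in
  climatically suitable places count less;
* for every (algorithm, pseudo-absence set, cross-validation run) triple,
  fit a probabilistic classifier on a stratified 70/30 split and score the
  held-out 30 % by the true skill statistic (TSS = sensitivity +
  specificity - 1) maximized over a cutoff lattice;
* keep members with TSS >= 0.7, falling back to the top 10 % when none
  qualifies;
* committee-average the members' binarized maps into an ensemble
  suitability surface (the per-cell fraction of members voting presence),
  with a per-cell coefficient of variation as the agreement measure;
* re-binarize the ensemble at the TSS-maximizing cutoff and report the
  Table-style metrics (TSS, sensitivity, specificity, cutoff, mean CV,
  range filling).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import PolynomialFeatures, SplineTransformer, StandardScaler

from ._seeds import child_rng, child_seed
from .grids import RasterLayer, RasterStack

__all__ = [
    "PseudoAbsenceSet",
    "FittedMember",
    "EnsemblePrediction",
    "EnsembleSettings",
    "ALGORITHMS",
    "sample_pseudo_absences",
    "weight_pseudo_absences",
    "split_train_eval",
    "fit_member",
    "evaluate_binary",
    "select_members",
    "committee_average",
    "binarize_ensemble",
    "range_filling",
    "fit_ensemble",
]

ALGORITHMS = ("glm_logistic", "gam_spline", "fda", "gbm", "maxent_like")


@dataclass
class PseudoAbsenceSet:
    """One random pseudo-absence draw: cells plus per-cell weights in [0,1]."""

    id: int
    rows: np.ndarray
    cols: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=int)
        self.cols = np.asarray(self.cols, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if not (len(self.rows) == len(self.cols) == len(self.weights)):
            raise ValueError("rows/cols/weights length mismatch")
        if len(self.weights) and (self.weights.min() < 0 or self.weights.max() > 1):
            raise ValueError("weights must lie in [0,1]")

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class FittedMember:
    algorithm: str
    pa_set_id: int
    cv_run_id: int
    model: object
    eval_sensitivity: float
    eval_specificity: float
    eval_tss: float
    member_cutoff: float


@dataclass
class EnsemblePrediction:
    """Committee-averaged ensemble output plus Table-style metrics."""

    suitability: RasterLayer
    cv: RasterLayer
    binary: RasterLayer
    cutoff: float
    tss: float
    sensitivity: float
    specificity: float
    mean_cv: float
    range_filling: float | None
    n_members_used: int
    n_presences: int
    member_tss: list[float] = field(default_factory=list)

    def metrics_row(self) -> dict:
        return {
            "n": self.n_presences,
            "TSS": self.tss,
            "Sensitivity": self.sensitivity,
            "Specificity": self.specificity,
            "Cut-off binary": self.cutoff,
            "Mean CV": self.mean_cv,
            "Range filling": self.range_filling,
        }


@dataclass
class EnsembleSettings:
    """Knobs of the per-tier ensemble; defaults mirror the full-scale study.

    ``n_pseudo_absences`` defaults to the global-tier 20 000 (use 5 000 for
    the regional tier); desk-scale runs shrink it via configuration.
    """

    algorithms: tuple[str, ...] = ("glm_logistic", "gam_spline", "fda", "gbm")
    include_maxent_like: bool = False
    n_pa_sets: int = 3
    n_cv_runs: int = 4
    n_pseudo_absences: int = 20_000
    train_fraction: float = 0.7
    tss_min: float = 0.7
    fallback_quantile: float = 0.10
    cutoff_step: float = 0.01
    gbm_n_estimators: int = 1000
    gbm_learning_rate: float = 0.01
    gbm_max_depth: int = 3
    min_presences: int = 30

    def roster(self) -> tuple[str, ...]:
        algs = tuple(self.algorithms)
        if self.include_maxent_like and "maxent_like" not in algs:
            algs = algs + ("maxent_like",)
        return algs


def cutoff_lattice(step: float = 0.01) -> np.ndarray:
    n = int(round(1.0 / step))
    return np.round(np.linspace(0.0, 1.0, n + 1), 10)


# ---------------------------------------------------------------------------
# pseudo-absences

def sample_pseudo_absences(
    region_mask: RasterLayer,
    n: int,
    presence_cells: set[tuple[int, int]],
    seed: int,
    pa_id: int = 1,
) -> PseudoAbsenceSet:
    """Uniform sample, without replacement, of non-presence valid cells."""
    valid = region_mask.valid.copy()
    for r, c in presence_cells:
        valid[r, c] = False
    rows, cols = np.nonzero(valid)
    if len(rows) < n:
        raise ValueError(
            f"requested {n} pseudo-absences but only {len(rows)} candidate cells"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(rows), size=n, replace=False)
    return PseudoAbsenceSet(pa_id, rows[idx], cols[idx], np.ones(n))


def pseudo_absence_weight(proj_g: np.ndarray) -> np.ndarray:
    """Inverse-logistic pseudo-absence weight of a global suitability p.

    ``w = 1 / (1 + (p/(p-1))^2)`` with the limit w = 0 at p = 1.  Decreasing
    on [0,1]: w(0) = 1, w(0.5) = 0.5, w(1) = 0.
    """
    p = np.asarray(proj_g, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("projected suitability must lie in [0,1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = p / (p - 1.0)
        w = 1.0 / (1.0 + ratio**2)
    return np.where(p == 1.0, 0.0, w)


def weight_pseudo_absences(pa: PseudoAbsenceSet, proj_g: RasterLayer) -> PseudoAbsenceSet:
    """Attach inverse-logistic weights from a projected suitability layer."""
    p = proj_g.values[pa.rows, pa.cols]
    if np.any(~np.isfinite(p)):
        raise ValueError("projected suitability undefined at some pseudo-absence cells")
    return PseudoAbsenceSet(pa.id, pa.rows.copy(), pa.cols.copy(), pseudo_absence_weight(p))


# ---------------------------------------------------------------------------
# members

def split_train_eval(
    n_presences: int, n_pa: int, fraction: float = 0.7, seed: int = 0
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Class-stratified random split; returns (train, eval) index pairs.

    Each pair is (presence_indices, pa_indices).  The split is applied
    independently to presences and pseudo-absences so both classes keep the
    training fraction.
    """
    if n_presences < 10:
        raise ValueError(f"need >= 10 presences to split, got {n_presences}")
    rng = np.random.default_rng(seed)
    p_perm = rng.permutation(n_presences)
    a_perm = rng.permutation(n_pa)
    kp = int(round(fraction * n_presences))
    ka = int(round(fraction * n_pa))
    return (
        (np.sort(p_perm[:kp]), np.sort(a_perm[:ka])),
        (np.sort(p_perm[kp:]), np.sort(a_perm[ka:])),
    )


class _FDA(BaseEstimator):
    """Two-class flexible discriminant on a spline basis.

    Optimal scoring with two classes reduces to a (weighted) ridge
    regression of the class indicator on the basis expansion; predictions
    are clipped to [0,1].
    """

    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def fit(self, X, y, sample_weight=None):
        self.basis_ = SplineTransformer(n_knots=4, degree=3).fit(X)
        self.reg_ = Ridge(alpha=self.alpha)
        self.reg_.fit(self.basis_.transform(X), y, sample_weight=sample_weight)
        return self

    def predict_proba(self, X):
        p = np.clip(self.reg_.predict(self.basis_.transform(X)), 0.0, 1.0)
        return np.column_stack([1.0 - p, p])


def _make_learner(algorithm: str, seed: int, settings: EnsembleSettings) -> Pipeline:
    if algorithm == "glm_logistic":
        steps = [
            ("scale", StandardScaler()),
            ("poly", PolynomialFeatures(degree=2, include_bias=False)),
            ("clf", LogisticRegression(C=np.inf, max_iter=2000)),
        ]
    elif algorithm == "gam_spline":
        steps = [
            ("scale", StandardScaler()),
            ("spline", SplineTransformer(n_knots=5, degree=3)),
            ("clf", LogisticRegression(C=10.0, max_iter=2000)),
        ]
    elif algorithm == "fda":
        steps = [("scale", StandardScaler()), ("clf", _FDA())]
    elif algorithm == "gbm":
        steps = [
            (
                "clf",
                GradientBoostingClassifier(
                    n_estimators=settings.gbm_n_estimators,
                    learning_rate=settings.gbm_learning_rate,
                    max_depth=settings.gbm_max_depth,
                    random_state=seed,
                ),
            )
        ]
    elif algorithm == "maxent_like":
        steps = [
            ("scale", StandardScaler()),
            ("poly", PolynomialFeatures(degree=2, include_bias=False)),
            ("clf", LogisticRegression(l1_ratio=1.0, solver="saga", C=1.0, max_iter=2000)),
        ]
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}; known: {ALGORITHMS}")
    return Pipeline(steps)


def fit_member(
    algorithm: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    w_train: np.ndarray,
    X_eval: np.ndarray,
    y_eval: np.ndarray,
    settings: EnsembleSettings | None = None,
    seed: int = 0,
    pa_set_id: int = 0,
    cv_run_id: int = 0,
) -> FittedMember:
    """Fit one weighted classifier and score it on held-out data.

    Pseudo-absence weights enter the loss as multiplicative case weights
    (presences carry weight 1); the member's own cutoff is the TSS-maximizing
    lattice value on the evaluation split.
    """
    settings = settings or EnsembleSettings()
    if len(np.unique(y_train)) < 2:
        raise ValueError("degenerate training data: a single class")
    model = _make_learner(algorithm, seed, settings)
    model.fit(X_train, y_train, clf__sample_weight=w_train)
    scores = model.predict_proba(X_eval)[:, 1]
    sens, spec, tss, cut = evaluate_binary(
        scores, y_eval, cutoff_lattice(settings.cutoff_step)
    )
    return FittedMember(
        algorithm=algorithm,
        pa_set_id=pa_set_id,
        cv_run_id=cv_run_id,
        model=model,
        eval_sensitivity=sens,
        eval_specificity=spec,
        eval_tss=tss,
        member_cutoff=cut,
    )


def evaluate_binary(
    scores: np.ndarray,
    labels: np.ndarray,
    lattice: np.ndarray | None = None,
) -> tuple[float, float, float, float]:
    """TSS-maximizing threshold search over a cutoff lattice.

    Returns (sensitivity, specificity, tss, best_cutoff) at the lattice
    value maximizing TSS; ties take the smallest cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("labels must contain both classes")
    if lattice is None:
        lattice = cutoff_lattice()
    pos = scores[labels]
    neg = scores[~labels]
    pred = pos[None, :] >= lattice[:, None]
    sens = pred.mean(axis=1)
    spec = (neg[None, :] < lattice[:, None]).mean(axis=1)
    tss = sens + spec - 1.0
    best = int(np.argmax(tss))  # argmax -> first (smallest) cutoff on ties
    return float(sens[best]), float(spec[best]), float(tss[best]), float(lattice[best])


def select_members(
    members: list[FittedMember],
    tss_min: float = 0.7,
    fallback_quantile: float = 0.10,
) -> list[FittedMember]:
    """Keep members with TSS >= tss_min; else the top-quantile best ones.

    The fallback keeps ``ceil(fallback_quantile * N)`` members ranked by
    evaluation TSS (stable order on ties), so the selection is never empty.
    """
    if not members:
        raise ValueError("no members to select from")
    good = [m for m in members if m.eval_tss >= tss_min]
    if good:
        return good
    k = max(1, int(np.ceil(fallback_quantile * len(members))))
    order = np.argsort([-m.eval_tss for m in members], kind="stable")
    return [members[i] for i in order[:k]]


# ---------------------------------------------------------------------------
# ensemble

def committee_average(
    members: list[FittedMember], stack: RasterStack
) -> tuple[RasterLayer, RasterLayer]:
    """Committee-average the members' binarized maps over a predictor stack.

    Each member's continuous prediction is binarized at its own cutoff; the
    ensemble suitability is the per-cell mean of those binaries (the vote
    fraction) and the CV layer is the per-cell population sd / mean of the
    binaries, set to 0 where the mean is 0 and rescaled to [0,1] by the
    maximum finite value on the map.
    """
    if not members:
        raise ValueError("empty member list")
    valid = stack.valid_mask()
    rows, cols = np.nonzero(valid)
    X = stack.table(rows, cols)
    binaries = np.empty((len(members), len(rows)))
    for i, m in enumerate(members):
        scores = m.model.predict_proba(X)[:, 1]
        binaries[i] = (scores >= m.member_cutoff).astype(float)
    mean = binaries.mean(axis=0)
    sd = binaries.std(axis=0)  # population sd
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), 0.0)
    max_cv = cv.max() if len(cv) else 0.0
    if max_cv > 0:
        cv = cv / max_cv

    def to_layer(flat: np.ndarray, name: str) -> RasterLayer:
        arr = np.full(stack.grid.shape, np.nan)
        arr[rows, cols] = flat
        return RasterLayer(stack.grid, name, arr, ~valid)

    return to_layer(mean, "suitability"), to_layer(cv, "cv")


def binarize_ensemble(
    suitability: RasterLayer,
    presence_cells: set[tuple[int, int]],
    pa: PseudoAbsenceSet,
    step: float = 0.01,
) -> tuple[RasterLayer, float, float, float, float]:
    """TSS-optimal binary map of the ensemble against presences + pseudo-absences."""
    pr, pc = zip(*sorted(presence_cells))
    pos = suitability.values[list(pr), list(pc)]
    neg = suitability.values[pa.rows, pa.cols]
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(len(pos), bool), np.zeros(len(neg), bool)])
    ok = np.isfinite(scores)
    sens, spec, tss, cut = evaluate_binary(scores[ok], labels[ok], cutoff_lattice(step))
    binary = np.where(suitability.mask, np.nan, (suitability.values >= cut).astype(float))
    layer = RasterLayer(suitability.grid, "binary", binary, suitability.mask.copy())
    return layer, cut, tss, sens, spec


def range_filling(binary: RasterLayer, presence_cells: set[tuple[int, int]]) -> float | None:
    """Fraction of predicted-presence cells that hold an observed presence.

    Returns None (undefined) when the predicted range is empty.
    """
    rows, cols = np.nonzero((binary.values == 1) & binary.valid)
    if len(rows) == 0:
        return None
    predicted = set(zip(rows.tolist(), cols.tolist()))
    return len(predicted & presence_cells) / len(predicted)


def fit_ensemble(
    presence_cells: set[tuple[int, int]],
    stack: RasterStack,
    settings: EnsembleSettings,
    master_seed: int,
    species: str = "",
    tier: str = "",
    pa_weights_from: RasterLayer | None = None,
) -> EnsemblePrediction:
    """Full per-species, per-tier ensemble fit.

    Draws ``n_pa_sets`` pseudo-absence sets (weighted through
    ``pa_weights_from`` when given), fits the algorithm roster across
    cross-validation runs, selects members, committee-averages, binarizes
    and computes the metrics table row.
    """
    if len(presence_cells) < settings.min_presences:
        raise ValueError(
            f"{species or 'species'}: {len(presence_cells)} presences "
            f"< minimum {settings.min_presences}"
        )
    valid = stack.valid_mask()
    region = RasterLayer(
        stack.grid, "region", np.where(valid, 1.0, np.nan), ~valid
    )

    pr, pc = zip(*sorted(presence_cells))
    pr = np.array(pr)
    pc = np.array(pc)
    X_pres = stack.table(pr, pc)

    pa_sets: list[PseudoAbsenceSet] = []
    for s in range(settings.n_pa_sets):
        pa = sample_pseudo_absences(
            region,
            settings.n_pseudo_absences,
            presence_cells,
            seed=child_seed(master_seed, species, tier, "pa", s + 1),
            pa_id=s + 1,
        )
        if pa_weights_from is not None:
            pa = weight_pseudo_absences(pa, pa_weights_from)
        pa_sets.append(pa)

    members: list[FittedMember] = []
    lattice = cutoff_lattice(settings.cutoff_step)
    for pa in pa_sets:
        X_pa = stack.table(pa.rows, pa.cols)
        for run in range(settings.n_cv_runs):
            split_seed = child_seed(master_seed, species, tier, "cv", pa.id, run + 1)
            (tp, ta), (ep, ea) = split_train_eval(
                len(pr), len(pa), settings.train_fraction, split_seed
            )
            X_train = np.vstack([X_pres[tp], X_pa[ta]])
            y_train = np.concatenate([np.ones(len(tp)), np.zeros(len(ta))])
            w_train = np.concatenate([np.ones(len(tp)), pa.weights[ta]])
            X_eval = np.vstack([X_pres[ep], X_pa[ea]])
            y_eval = np.concatenate([np.ones(len(ep)), np.zeros(len(ea))])
            for alg in settings.roster():
                members.append(
                    fit_member(
                        alg,
                        X_train,
                        y_train,
                        w_train,
                        X_eval,
                        y_eval,
                        settings=settings,
                        seed=child_seed(master_seed, species, tier, alg, pa.id, run + 1),
                        pa_set_id=pa.id,
                        cv_run_id=run + 1,
                    )
                )

    selected = select_members(members, settings.tss_min, settings.fallback_quantile)
    suitability, cv = committee_average(selected, stack)
    binary, cut, tss, sens, spec = binarize_ensemble(
        suitability, presence_cells, pa_sets[0], settings.cutoff_step
    )
    rf = range_filling(binary, presence_cells)
    return EnsemblePrediction(
        suitability=suitability,
        cv=cv,
        binary=binary,
        cutoff=cut,
        tss=tss,
        sensitivity=sens,
        specificity=spec,
        mean_cv=float(np.nanmean(cv.valid_values)) if cv.valid.any() else float("nan"),
        range_filling=rf,
        n_members_used=len(selected),
        n_presences=len(presence_cells),
        member_tss=[m.eval_tss for m in members],
    )
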