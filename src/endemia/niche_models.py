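"""Calibration regions, pseudo-absence sampling, niche-model algorithms, and
TSS/ROC evaluation.

The calibration region M of a species is the intersection of a 4-degree
buffer around its occurrences with the ecoregions it occupies; projections
use a projected M, a 2-degree dilation of M, under a full-dispersal
assumption. Models are presence / pseudo-absence classifiers trained at
prevalence 0.5 (total presence weight = total absence weight) on stratified
70/30 replicate splits.

Five algorithm families share one fit/predict contract, chosen to retain the
heterogeneity of a multi-algorithm ensemble at desk scale:

``envelope``
    percentile surface-range envelope (presence box between the 2.5th and
    97.5th percentile per predictor; binary score).
``logistic``
    penalized logistic regression on linear + quadratic features.
``tree``
    depth-capped classification tree.
``bagged_trees``
    random forest (bagged trees with feature subsampling).
``maxent_like``
    exponential-family density-ratio model on linear + quadratic features,
    fitted by maximizing the presence log-likelihood of a Gibbs distribution
    over the background cells (the core of the Maxent formulation).

Evaluation uses the area under the ROC curve (pairwise concordance with ties
counted 1/2) and the True Skill Statistic maximized over the threshold grid
{0.00, 0.01, ..., 1.00}, ties broken toward the lowest threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import expit, logsumexp
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier

from .data_prep import SpeciesRecordSet, dilate_cells
from .synthetic_world import ClimateStack, WorldMask, subseed

ALGORITHMS = ("envelope", "logistic", "tree", "bagged_trees", "maxent_like")

TSS_THRESHOLD_GRID = np.round(np.arange(0, 101) / 100.0, 2)


@dataclass
class CalibrationRegion:
    species_id: str
    m_cells: np.ndarray  # sorted flat indices
    projected_m_cells: np.ndarray
    fallback_used: bool = False


@dataclass
class TrainingSet:
    """Presences plus pseudo-absences with prevalence-0.5 weights."""

    presence_cells: np.ndarray
    absence_cells: np.ndarray
    presence_weights: np.ndarray
    absence_weights: np.ndarray

    @property
    def n_presence(self) -> int:
        return self.presence_cells.size

    @property
    def n_absence(self) -> int:
        return self.absence_cells.size


@dataclass
class EvaluationResult:
    tss: float
    auc: float
    tss_threshold: float
    sensitivity: float
    specificity: float


@dataclass
class AlgorithmFit:
    """A fitted niche model with a uniform predict contract.

    Features are standardized with the training-region statistics stored in
    ``means``/``sds`` (reused unchanged when projecting onto future climates).
    """

    algorithm_id: str
    replicate_index: int
    kept_layers: list[str]
    means: np.ndarray
    sds: np.ndarray
    params: dict = field(repr=False)
    seed: int = 0
    converged: bool = True

    def predict_matrix(self, x_raw: np.ndarray) -> np.ndarray:
        """Suitability in [0, 1] for rows of raw predictor values."""
        z = (x_raw - self.means) / self.sds
        a = self.algorithm_id
        if a == "envelope":
            inside = (x_raw >= self.params["lower"]) & (x_raw <= self.params["upper"])
            return inside.all(axis=1).astype(float)
        if a in ("logistic", "tree", "bagged_trees"):
            model = self.params["model"]
            feats = _quadratic_features(z) if a == "logistic" else z
            return np.clip(model.predict_proba(feats)[:, 1], 0.0, 1.0)
        if a == "maxent_like":
            eta = _quadratic_features(z) @ self.params["lam"] - self.params["offset"]
            return expit(eta)
        raise ValueError(f"unknown algorithm {a!r}")

    def predict_cells(self, stack: ClimateStack, cells: np.ndarray) -> np.ndarray:
        return self.predict_matrix(stack.matrix(cells, self.kept_layers))


def _quadratic_features(z: np.ndarray) -> np.ndarray:
    return np.column_stack([z, z * z])


# ---------------------------------------------------------------------------
# calibration regions
# ---------------------------------------------------------------------------

def build_m(
    s: SpeciesRecordSet, mask: WorldMask, buffer_deg: float = 4.0
) -> CalibrationRegion:
    """Accessible area M = occurrence buffer intersected with occupied ecoregions.

    If M would be too small to sample pseudo-absences (|M| <= |presences|+1),
    the fallback used for problematic insular species applies: M becomes the
    whole country holding the occurrences.
    """
    if not s.retained:
        raise ValueError(f"{s.species_id} is not retained")
    grid = mask.grid
    radius = grid.degrees_to_cells(buffer_deg)
    occ = np.zeros(grid.shape, dtype=bool)
    rows, cols = grid.unravel(s.unique_cells)
    occ[rows, cols] = True
    buffered = dilate_cells(occ, radius)
    occupied_eco = np.unique(mask.ecoregion_id[rows, cols])
    occupied_eco = occupied_eco[occupied_eco > 0]
    in_eco = np.isin(mask.ecoregion_id, occupied_eco)
    m = buffered & in_eco & mask.land
    m_cells = np.flatnonzero(m.ravel())
    fallback = False
    if m_cells.size <= s.unique_cells.size + 1:
        countries = mask.country_id[rows, cols]
        home = int(np.bincount(countries[countries > 0]).argmax())
        m_cells = mask.country_cells(home)
        fallback = True
    return CalibrationRegion(
        species_id=s.species_id,
        m_cells=m_cells,
        projected_m_cells=m_cells,
        fallback_used=fallback,
    )


def build_projected_m(
    cr: CalibrationRegion, mask: WorldMask, buffer_deg: float = 2.0
) -> CalibrationRegion:
    """Dilate M by the projection buffer (full-dispersal area), clipped to land."""
    grid = mask.grid
    radius = grid.degrees_to_cells(buffer_deg)
    m = np.zeros(grid.shape, dtype=bool)
    rows, cols = grid.unravel(cr.m_cells)
    m[rows, cols] = True
    proj = dilate_cells(m, radius) & mask.land
    cr.projected_m_cells = np.flatnonzero(proj.ravel())
    return cr


# ---------------------------------------------------------------------------
# training data
# ---------------------------------------------------------------------------

def draw_pseudo_absences(
    cr: CalibrationRegion,
    presences: np.ndarray,
    n: int = 10000,
    seed: int = 0,
) -> TrainingSet:
    """Sample pseudo-absences uniformly from M excluding presence cells.

    Weights realize prevalence 0.5: each presence has weight 1 and each
    absence weight n_presence/n_absence, so both classes carry equal total
    weight in every fit.
    """
    presences = np.asarray(presences)
    pool = np.setdiff1d(cr.m_cells, presences)
    if pool.size == 0:
        raise ValueError(f"{cr.species_id}: empty pseudo-absence pool (M == presences)")
    rng = np.random.default_rng(subseed(seed, "pa", cr.species_id))
    k = min(n, pool.size)
    absences = np.sort(rng.choice(pool, size=k, replace=False))
    w_abs = presences.size / absences.size
    return TrainingSet(
        presence_cells=np.sort(presences),
        absence_cells=absences,
        presence_weights=np.ones(presences.size),
        absence_weights=np.full(absences.size, w_abs),
    )


def split_replicates(
    ts: TrainingSet,
    fraction: float = 0.7,
    n_reps: int = 10,
    seed: int = 0,
) -> list[tuple[TrainingSet, TrainingSet]]:
    """Stratified random train/test splits, 70/30 by default, 10 replicates.

    Stratification is within presences and within absences separately, so the
    training prevalence matches the full set's. Weights are recomputed per
    subset to keep prevalence 0.5 exactly.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must lie strictly between 0 and 1")
    splits = []
    for rep in range(n_reps):
        rng = np.random.default_rng(subseed(seed, "split", rep))
        tr_p, te_p = _split_one(ts.presence_cells, fraction, rng)
        tr_a, te_a = _split_one(ts.absence_cells, fraction, rng)
        splits.append((_make_set(tr_p, tr_a), _make_set(te_p, te_a)))
    return splits


def _split_one(cells: np.ndarray, fraction: float, rng) -> tuple[np.ndarray, np.ndarray]:
    n_train = int(round(fraction * cells.size))
    n_train = min(max(n_train, 1), cells.size - 1)
    perm = rng.permutation(cells.size)
    return np.sort(cells[perm[:n_train]]), np.sort(cells[perm[n_train:]])


def _make_set(pres: np.ndarray, absn: np.ndarray) -> TrainingSet:
    return TrainingSet(
        presence_cells=pres,
        absence_cells=absn,
        presence_weights=np.ones(pres.size),
        absence_weights=np.full(absn.size, pres.size / max(absn.size, 1)),
    )


# ---------------------------------------------------------------------------
# algorithms
# ---------------------------------------------------------------------------

def fit_algorithm(
    train: TrainingSet,
    stack: ClimateStack,
    kept_layers: list[str],
    algorithm_id: str,
    seed: int = 0,
    envelope_window: tuple[float, float] = (2.5, 97.5),
) -> AlgorithmFit:
    """Fit one algorithm on a training set; deterministic given the seed."""
    if algorithm_id not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm_id!r}; choose from {ALGORITHMS}")
    if train.n_presence < 2 or train.n_absence < 2:
        raise ValueError(
            f"degenerate training set: {train.n_presence} presences, "
            f"{train.n_absence} absences (need >= 2 of each)"
        )
    xp = stack.matrix(train.presence_cells, kept_layers)
    xa = stack.matrix(train.absence_cells, kept_layers)
    x = np.vstack([xp, xa])
    means = x.mean(axis=0)
    sds = np.maximum(x.std(axis=0), 1e-12)
    y = np.concatenate([np.ones(train.n_presence), np.zeros(train.n_absence)])
    w = np.concatenate([train.presence_weights, train.absence_weights])
    converged = True

    if algorithm_id == "envelope":
        lo, hi = envelope_window
        params = {
            "lower": np.percentile(xp, lo, axis=0),
            "upper": np.percentile(xp, hi, axis=0),
            "window": envelope_window,
        }
    elif algorithm_id == "logistic":
        z = (x - means) / sds
        model = LogisticRegression(C=10.0, max_iter=1000)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            model.fit(_quadratic_features(z), y, sample_weight=w)
        converged = not any("onverge" in str(c.message) for c in caught)
        params = {"model": model}
    elif algorithm_id == "tree":
        model = DecisionTreeClassifier(max_depth=8, random_state=seed)
        model.fit((x - means) / sds, y, sample_weight=w)
        params = {"model": model}
    elif algorithm_id == "bagged_trees":
        model = RandomForestClassifier(
            n_estimators=80, max_features="sqrt", random_state=seed, n_jobs=1
        )
        model.fit((x - means) / sds, y, sample_weight=w)
        params = {"model": model}
    else:  # maxent_like
        lam, offset, converged = _fit_maxent(
            (xp - means) / sds, (xa - means) / sds
        )
        params = {"lam": lam, "offset": offset}

    return AlgorithmFit(
        algorithm_id=algorithm_id,
        replicate_index=0,
        kept_layers=list(kept_layers),
        means=means,
        sds=sds,
        params=params,
        seed=seed,
        converged=converged,
    )


def _fit_maxent(
    zp: np.ndarray, zbg: np.ndarray, alpha: float = 0.005, max_iter: int = 300
) -> tuple[np.ndarray, float, bool]:
    """Fit the Gibbs density-ratio model by penalized maximum likelihood.

    Minimizes -mean_presence(phi @ lam) + log mean_background exp(phi @ lam)
    + alpha ||lam||^2, i.e. the Maxent objective with the background cells as
    the normalizing distribution and an L2 ridge for stability. The returned
    offset centers the linear predictor at the background log-mean, so a cell
    climatically indistinguishable from background scores ~0.5.
    """
    fp = _quadratic_features(zp)
    fbg = _quadratic_features(zbg)
    mean_fp = fp.mean(axis=0)
    log_nbg = np.log(fbg.shape[0])

    def objective(lam: np.ndarray) -> tuple[float, np.ndarray]:
        s = fbg @ lam
        lz = logsumexp(s) - log_nbg
        p = np.exp(s - lz - log_nbg)  # background Gibbs weights, sum to 1
        val = -float(mean_fp @ lam) + lz + alpha * float(lam @ lam)
        grad = -mean_fp + p @ fbg + 2 * alpha * lam
        return val, grad

    res = optimize.minimize(
        objective,
        np.zeros(fp.shape[1]),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter},
    )
    lam = res.x
    offset = float(logsumexp(fbg @ lam) - log_nbg)
    return lam, offset, bool(res.success)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def auc_score(presence_scores: np.ndarray, absence_scores: np.ndarray) -> float:
    """Pairwise-concordance AUC with ties counted 1/2 (Mann-Whitney)."""
    p = np.asarray(presence_scores, dtype=float)
    a = np.asarray(absence_scores, dtype=float)
    ranks = rankdata(np.concatenate([p, a]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * a.size))


def evaluate(presence_scores, absence_scores) -> EvaluationResult:
    """AUC plus the TSS maximized over the 101-point threshold grid.

    A cell counts as predicted-presence when its score is >= the threshold.
    TSS ties are broken toward the lowest threshold.
    """
    p = np.asarray(presence_scores, dtype=float)
    a = np.asarray(absence_scores, dtype=float)
    if p.size == 0 or a.size == 0:
        raise ValueError("both score lists must be non-empty")
    sens = (p[None, :] >= TSS_THRESHOLD_GRID[:, None]).mean(axis=1)
    spec = (a[None, :] < TSS_THRESHOLD_GRID[:, None]).mean(axis=1)
    tss = sens + spec - 1.0
    best = int(np.argmax(tss))  # argmax returns the first (lowest) maximizer
    return EvaluationResult(
        tss=float(tss[best]),
        auc=auc_score(p, a),
        tss_threshold=float(TSS_THRESHOLD_GRID[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
    )


def variable_contributions(
    fit: AlgorithmFit,
    train: TrainingSet,
    stack: ClimateStack,
    n_permutations: int = 5,
    seed: int = 0,
    max_cells_per_class: int = 500,
) -> list[tuple[str, float]]:
    """Permutation importance: drop in training AUC when a layer is shuffled.

    The mean drop over ``n_permutations`` seeded shuffles is reported per
    layer, descending. Importance is evaluated on a balanced subsample of at
    most ``max_cells_per_class`` training cells per class to keep the cost of
    per-replicate importances negligible.
    """
    rng = np.random.default_rng(subseed(seed, "contrib", fit.algorithm_id, fit.replicate_index))
    pres = train.presence_cells
    absn = train.absence_cells
    if pres.size > max_cells_per_class:
        pres = np.sort(rng.choice(pres, size=max_cells_per_class, replace=False))
    if absn.size > max_cells_per_class:
        absn = np.sort(rng.choice(absn, size=max_cells_per_class, replace=False))
    xp = stack.matrix(pres, fit.kept_layers)
    xa = stack.matrix(absn, fit.kept_layers)
    x = np.vstack([xp, xa])
    base = auc_score(fit.predict_matrix(xp), fit.predict_matrix(xa))
    out = []
    for j, layer in enumerate(fit.kept_layers):
        drops = []
        for _ in range(n_permutations):
            xq = x.copy()
            xq[:, j] = rng.permutation(xq[:, j])
            scores = fit.predict_matrix(xq)
            drops.append(base - auc_score(scores[: pres.size], scores[pres.size:]))
        out.append((layer, float(np.mean(drops))))
    out.sort(key=lambda t: -t[1])
    return out
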