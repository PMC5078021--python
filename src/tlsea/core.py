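"""The two-layer similarity-ensemble statistic (TL-SEA).

Layer 1 scores each phenotype-active compound against one protein's ligand
set: the initial score I_i sums the ligand-compound similarities that exceed
a noise threshold (0.15), is standardized to Z_i = (I_i - k*m) / (a * m**b)
using background constants fitted against the ligand-set size m, and is
converted to an empirical tail probability P_Z against a pool of random-set
Z scores. Layer 2 aggregates a protein's Z vector into an original score
O = sum of Z >= c (c is the Z value whose background tail probability equals
alpha_z) and converts O to the association score P_O against a second pool
built from random pseudo ligand sets.

Both null pools derive from a single random background similarity matrix M_r.
The background model mu_m = k*m, sigma_m = a*m**b is the ligand-set-size
scaling law of the similarity ensemble approach: the supra-threshold
similarity sum grows linearly in the number of ligands while its spread
grows almost linearly, so Z is comparable across proteins with very
different ligand-set sizes.

Empirical p-values are tail fractions with ties included; a score exceeding
every pool member is reported as "< 1/N" and carried numerically as 0.5/N so
that sorting and network weights stay finite and order-consistent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .filtering import LigandSet
from .io import RunConfig
from .similarity import SimilarityMatrix, slice_target_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "InitialScoreVector",
    "BackgroundSamples",
    "BackgroundFit",
    "ZPool",
    "OPool",
    "ProteinAssociation",
    "AssociationResult",
    "TwoLayerSEA",
    "initial_score",
    "sample_background_initial_scores",
    "fit_background",
    "z_transform",
    "build_z_pool",
    "p_z",
    "z_threshold",
    "original_score",
    "sample_background_original_scores",
    "p_o",
    "associate",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class InitialScoreVector:
    """Per phenotype-compound initial scores I for one protein; m is the
    ligand-set size (row count of M_t)."""

    protein_id: str
    m: int
    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if np.any(self.scores < 0) or np.any(self.scores > self.m):
            raise ValueError("initial scores must lie in [0, m]")


@dataclass
class BackgroundSamples:
    """Random-set initial scores tagged by their sampling length m."""

    lengths: np.ndarray  # (n_samples,), int
    scores: np.ndarray  # (n_samples,), float
    sim_threshold: float

    def __post_init__(self):
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.lengths.shape != self.scores.shape:
            raise ValueError("lengths and scores must align")

    @property
    def size(self) -> int:
        return self.scores.size

    def by_length(self) -> dict[int, np.ndarray]:
        order = np.argsort(self.lengths, kind="stable")
        lengths, scores = self.lengths[order], self.scores[order]
        uniq, starts = np.unique(lengths, return_index=True)
        bounds = list(starts[1:]) + [lengths.size]
        return {int(m): scores[s:e] for m, s, e in zip(uniq, starts, bounds)}


@dataclass
class BackgroundFit:
    """Fitted background constants and the per-length moments behind them.

    k_hat comes from a least-squares fit of the group means through the
    origin (mu_m = k*m); a_hat and b_hat from an ordinary least-squares line
    in log-log space over groups with positive SD (sigma_m = a * m**b).
    """

    k_hat: float
    a_hat: float
    b_hat: float
    length_grid: np.ndarray
    mu_by_length: np.ndarray
    sigma_by_length: np.ndarray
    meta: dict = field(default_factory=dict)

    def mu(self, m) -> np.ndarray | float:
        return self.k_hat * np.asarray(m, dtype=float)

    def sigma(self, m) -> np.ndarray | float:
        return self.a_hat * np.asarray(m, dtype=float) ** self.b_hat


class _TailPool:
    """Sorted empirical null pool with inclusive tail probabilities."""

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=np.float64)
        if values.size == 0:
            raise ValueError("empty null pool")
        self._sorted = np.sort(values)

    @property
    def size(self) -> int:
        return self._sorted.size

    @property
    def resolution(self) -> float:
        """Smallest resolvable nonzero p-value, 1/N."""
        return 1.0 / self.size

    def min(self) -> float:
        return float(self._sorted[0])

    def max(self) -> float:
        return float(self._sorted[-1])

    def tail_p(self, score):
        """Fraction of pool values >= score (ties inclusive). Scores beyond
        the pool maximum are reported as 0.5/N, standing for "< 1/N"."""
        score = np.asarray(score, dtype=np.float64)
        n = self.size
        count = n - np.searchsorted(self._sorted, score, side="left")
        p = np.where(count > 0, count / n, 0.5 / n)
        return float(p) if p.ndim == 0 else p

    def tail_p_randomized(self, score, rng: np.random.Generator):
        """Tie-randomized tail probability, the calibration diagnostic for a
        discrete statistic: p* = (n_gt + U * (n_ge - n_gt + 1)) / (N + 1)
        with U ~ Uniform(0,1). When the score is an independent draw from
        the pool's own distribution, p* is exactly Uniform(0,1), so
        uniformity checks are not distorted by pool ties (e.g. the atom at
        an original score of zero)."""
        score = np.asarray(score, dtype=np.float64)
        n = self.size
        n_ge = n - np.searchsorted(self._sorted, score, side="left")
        n_gt = n - np.searchsorted(self._sorted, score, side="right")
        u = rng.random(size=score.shape)
        p = (n_gt + u * (n_ge - n_gt + 1)) / (n + 1)
        return float(p) if p.ndim == 0 else p


class ZPool(_TailPool):
    """Null population of standardized scores Z_r."""

    def __init__(self, z_values: np.ndarray):
        super().__init__(z_values)

    @property
    def z_values(self) -> np.ndarray:
        return self._sorted


class OPool(_TailPool):
    """Null population of original scores O_r, with the Z threshold used."""

    def __init__(self, o_values: np.ndarray, c: float):
        super().__init__(o_values)
        self.c = float(c)

    @property
    def o_values(self) -> np.ndarray:
        return self._sorted


@dataclass
class ProteinAssociation:
    protein_id: str
    m: int
    initial_scores: np.ndarray
    z_scores: np.ndarray
    p_z: np.ndarray
    o_score: float
    p_o: float
    rank: int = 0


@dataclass
class AssociationResult:
    """Full output of one association run: the compound x protein P_Z matrix
    and the per-protein association (AS) scores with ranks."""

    col_ids: list[str]
    proteins: list[ProteinAssociation]
    c: float
    pz_resolution: float
    po_resolution: float
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def pz_matrix(self):
        import pandas as pd

        data = {p.protein_id: p.p_z for p in self.proteins}
        return pd.DataFrame(data, index=self.col_ids)

    def protein(self, protein_id: str) -> ProteinAssociation:
        for p in self.proteins:
            if p.protein_id == protein_id:
                return p
        raise KeyError(protein_id)


# ---------------------------------------------------------------------------
# layer-1 primitives


def initial_score(
    M_t: SimilarityMatrix, sim_threshold: float = 0.15, protein_id: str = ""
) -> InitialScoreVector:
    """Initial score per column: I_i = sum_j S_ji for S_ji strictly above the
    similarity threshold."""
    if M_t.values.size == 0:
        raise ValueError("empty target sub-matrix")
    v = M_t.values
    scores = np.where(v > sim_threshold, v, 0.0).sum(axis=0)
    return InitialScoreVector(protein_id, v.shape[0], scores)


def _draw_lengths(rng: np.random.Generator, n_lengths: int, length_range) -> np.ndarray:
    """Distinct sampling lengths when the range allows, repeats otherwise."""
    lo, hi = int(length_range[0]), int(length_range[1])
    n_avail = hi - lo + 1
    if n_lengths <= n_avail:
        return np.sort(rng.choice(np.arange(lo, hi + 1), size=n_lengths, replace=False))
    return np.sort(rng.integers(lo, hi + 1, size=n_lengths))


def _sample_initial_matrix(
    v_thr: np.ndarray, m: int, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Initial scores of `reps` random pseudo ligand sets of size m, for every
    column at once; shape (reps, n_cols).

    Rows are drawn without replacement while m fits in the matrix and with
    replacement beyond that, so small fixtures and the large-length regime
    are both handled. Row-membership indicator (or multiplicity) matrices
    keep the cost linear in the matrix size instead of in m.
    """
    n_rows = v_thr.shape[0]
    if m < n_rows:
        r = rng.random((reps, n_rows))
        rows = np.argpartition(r, m, axis=1)[:, :m]
        sel = np.zeros((reps, n_rows))
        np.put_along_axis(sel, rows, 1.0, axis=1)
    elif m == n_rows:
        sel = np.ones((reps, n_rows))
    else:
        sel = rng.multinomial(m, np.full(n_rows, 1.0 / n_rows), size=reps).astype(np.float64)
    return sel @ v_thr


def sample_background_initial_scores(
    M_r: SimilarityMatrix, config: RunConfig, rng: np.random.Generator | int | None = None
) -> BackgroundSamples:
    """Column-sampling null: for each of n_lengths random lengths m and each
    repetition, draw one column of M_r and m random rows, and record the
    initial score of the column over those rows."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n_rows, n_cols = M_r.shape
    if n_rows < 1:
        raise ValueError("random background matrix has no rows")
    reps = config.reps_per_length
    v_thr = np.where(M_r.values > config.sim_threshold, M_r.values, 0.0)
    lengths = _draw_lengths(rng, config.n_lengths, config.length_range)

    all_lengths = np.repeat(lengths, reps)
    all_scores = np.empty(all_lengths.size)
    cycle_pos = 0
    for idx, m in enumerate(lengths):
        i_mat = _sample_initial_matrix(v_thr, int(m), reps, rng)
        if config.column_mode == "cycle":
            cols = (cycle_pos + np.arange(reps)) % n_cols
            cycle_pos = (cycle_pos + reps) % n_cols
        else:
            cols = rng.integers(0, n_cols, size=reps)
        all_scores[idx * reps : (idx + 1) * reps] = i_mat[np.arange(reps), cols]
    return BackgroundSamples(all_lengths, all_scores, config.sim_threshold)


def fit_background(samples: BackgroundSamples) -> BackgroundFit:
    """Fit mu_m = k*m and sigma_m = a*m**b to the per-length moments of the
    background initial scores.

    Groups with sigma_m = 0 cannot enter the log-log SD regression; if more
    than half the groups are degenerate the background carries too little
    supra-threshold similarity and the fit errors out.
    """
    groups = samples.by_length()
    if len(groups) < 2:
        raise ValueError("background fit needs samples at >= 2 distinct lengths")
    for m, vals in groups.items():
        if vals.size < 2:
            raise ValueError(f"length group m={m} has fewer than 2 samples")

    ms = np.array(sorted(groups), dtype=np.float64)
    mu = np.array([groups[int(m)].mean() for m in ms])
    sigma = np.array([groups[int(m)].std(ddof=1) for m in ms])

    pos = sigma > 0
    if not pos.any():
        raise ValueError("degenerate background (no supra-threshold similarity)")
    if pos.mean() < 0.5:
        raise ValueError(
            "more than half the length groups have zero SD; background too sparse"
        )

    k_hat = float(np.sum(mu * ms) / np.sum(ms * ms))
    fit = stats.linregress(np.log(ms[pos]), np.log(sigma[pos]))
    b_hat = float(fit.slope)
    a_hat = float(np.exp(fit.intercept))
    return BackgroundFit(
        k_hat,
        a_hat,
        b_hat,
        ms.astype(np.int64),
        mu,
        sigma,
        meta={
            "n_lengths": len(groups),
            "sim_threshold": samples.sim_threshold,
            "n_samples": samples.size,
            "sigma_groups_excluded": int((~pos).sum()),
        },
    )


def z_transform(I: InitialScoreVector, fit: BackgroundFit) -> np.ndarray:
    """Standardize an initial-score vector: Z = (I - k*m) / (a * m**b)."""
    return _z_values(I.scores, I.m, fit)


def _z_values(scores: np.ndarray, m, fit: BackgroundFit) -> np.ndarray:
    scale = fit.sigma(m)
    if np.any(np.asarray(scale) == 0):
        raise ZeroDivisionError("background SD model evaluates to 0 at this length")
    return (np.asarray(scores, dtype=np.float64) - fit.mu(m)) / scale


def build_z_pool(samples: BackgroundSamples, fit: BackgroundFit) -> ZPool:
    """Standardize every background initial score by its own sampling length."""
    return ZPool(_z_values(samples.scores, samples.lengths, fit))


def p_z(z_i, pool: ZPool):
    """Empirical tail probability of Z: the fraction of the null Z pool at or
    above z_i."""
    return pool.tail_p(z_i)


def z_threshold(pool: ZPool, alpha_z: float = 0.01) -> float:
    """The smallest pool value c whose tail probability is <= alpha_z.

    Summing Z >= c then collects exactly the scores individually significant
    at level alpha_z under the background null.
    """
    n = pool.size
    max_tail = int(np.floor(alpha_z * n + 1e-9))
    if max_tail < 1:
        raise ValueError(f"pool of {n} cannot resolve alpha_z={alpha_z}")
    sorted_vals = pool.z_values
    uniq, first = np.unique(sorted_vals, return_index=True)
    tail = n - first
    ok = tail <= max_tail
    if not ok.any():
        raise ValueError("no attainable threshold (too many ties at the pool maximum)")
    return float(uniq[np.argmax(ok)])


# ---------------------------------------------------------------------------
# layer-2 primitives


def original_score(z_vector: np.ndarray, c: float) -> float:
    """Original association score O: the sum of standardized scores at or
    above the significance threshold c."""
    z = np.asarray(z_vector, dtype=np.float64)
    if not np.isfinite(c):
        raise ValueError("threshold c must be finite")
    return float(z[z >= c].sum())


def sample_background_original_scores(
    M_r: SimilarityMatrix,
    fit: BackgroundFit,
    c: float,
    n_pheno: int,
    config: RunConfig,
    rng: np.random.Generator | int | None = None,
) -> OPool:
    """Row-sampling null: each repetition extracts m random rows of M_r as a
    pseudo ligand set, scores every column (Eq. 1 then the Z transform), and
    sums the Z values at or above c.

    Every O_r spans the full phenotype column set, the same length as the
    observed O scores, so no further standardization is applied.
    """
    n_rows, n_cols = M_r.shape
    if n_pheno != n_cols:
        raise ValueError(
            f"M_r has {n_cols} phenotype columns but n_pheno={n_pheno} was requested"
        )
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    reps = config.reps_per_length
    v_thr = np.where(M_r.values > config.sim_threshold, M_r.values, 0.0)
    length_range = config.o_length_range or config.length_range
    lengths = _draw_lengths(rng, config.n_lengths, length_range)

    o_values = np.empty(lengths.size * reps)
    for idx, m in enumerate(lengths):
        i_mat = _sample_initial_matrix(v_thr, int(m), reps, rng)
        z_mat = _z_values(i_mat, int(m), fit)
        o_values[idx * reps : (idx + 1) * reps] = np.where(z_mat >= c, z_mat, 0.0).sum(axis=1)
    return OPool(o_values, c)


def p_o(o: float, pool: OPool):
    """The association (AS) score: fraction of null original scores O_r at or
    above the observed O."""
    return pool.tail_p(o)


# ---------------------------------------------------------------------------
# the estimator


class TwoLayerSEA(BaseEstimator):
    """Two-layer similarity-ensemble association model.

    ``fit`` consumes a random background similarity matrix M_r and builds the
    full null machinery: the background constants (k, a, b), the standardized
    null pool for P_Z, the Z threshold c at level ``alpha_z``, and the
    original-score null pool for P_O. ``score_proteins`` then evaluates any
    number of protein ligand sets against a target similarity matrix M that
    shares M_r's phenotype columns.

    Parameters mirror :class:`tlsea.io.RunConfig`; ``random_state`` seeds all
    sampling through named substreams (background rows/columns, optional
    fresh Z pool, pseudo-ligand-set rows), so each stage is independently
    reproducible.
    """

    def __init__(
        self,
        sim_threshold: float = 0.15,
        alpha_z: float = 0.01,
        n_lengths: int = 200,
        reps_per_length: int = 500,
        length_range: tuple[int, int] = (1, 10_000),
        o_length_range: tuple[int, int] | None = None,
        column_mode: str = "redraw",
        reuse_fit_pool: bool = True,
        random_state: int | None = None,
    ):
        self.sim_threshold = sim_threshold
        self.alpha_z = alpha_z
        self.n_lengths = n_lengths
        self.reps_per_length = reps_per_length
        self.length_range = length_range
        self.o_length_range = o_length_range
        self.column_mode = column_mode
        self.reuse_fit_pool = reuse_fit_pool
        self.random_state = random_state

    @classmethod
    def from_config(cls, config: RunConfig) -> "TwoLayerSEA":
        return cls(
            sim_threshold=config.sim_threshold,
            alpha_z=config.alpha_z,
            n_lengths=config.n_lengths,
            reps_per_length=config.reps_per_length,
            length_range=config.length_range,
            o_length_range=config.o_length_range,
            column_mode=config.column_mode,
            reuse_fit_pool=config.reuse_fit_pool,
            random_state=config.seed,
        )

    def _config(self) -> RunConfig:
        return RunConfig(
            sim_threshold=self.sim_threshold,
            alpha_z=self.alpha_z,
            n_lengths=self.n_lengths,
            reps_per_length=self.reps_per_length,
            length_range=tuple(self.length_range),
            o_length_range=None if self.o_length_range is None else tuple(self.o_length_range),
            column_mode=self.column_mode,
            reuse_fit_pool=self.reuse_fit_pool,
            seed=0 if self.random_state is None else int(self.random_state),
        )

    @staticmethod
    def _as_matrix(X) -> SimilarityMatrix:
        if isinstance(X, SimilarityMatrix):
            return X
        values = np.asarray(X, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError("expected a 2-D similarity matrix")
        return SimilarityMatrix(
            [f"r{i}" for i in range(values.shape[0])],
            [f"c{i}" for i in range(values.shape[1])],
            values,
        )

    def fit(self, X, y=None) -> "TwoLayerSEA":
        """Fit the background model and both null pools on the random
        background similarity matrix ``X`` (M_r)."""
        M_r = self._as_matrix(X)
        config = self._config()
        ss = np.random.SeedSequence(self.random_state)
        s_bg, s_fresh, s_opool = ss.spawn(3)

        samples = sample_background_initial_scores(M_r, config, np.random.default_rng(s_bg))
        self.background_fit_ = fit_background(samples)
        if self.reuse_fit_pool:
            pool_samples = samples
        else:
            pool_samples = sample_background_initial_scores(
                M_r, config, np.random.default_rng(s_fresh)
            )
        self.z_pool_ = build_z_pool(pool_samples, self.background_fit_)
        self.c_ = z_threshold(self.z_pool_, self.alpha_z)
        self.o_pool_ = sample_background_original_scores(
            M_r,
            self.background_fit_,
            self.c_,
            M_r.shape[1],
            config,
            np.random.default_rng(s_opool),
        )
        self.n_features_in_ = M_r.shape[1]
        self.background_cols_ = list(M_r.col_ids)
        return self

    def _check_fitted(self):
        if not hasattr(self, "background_fit_"):
            raise RuntimeError("TwoLayerSEA instance is not fitted yet")

    def score_protein(self, M_t: SimilarityMatrix, protein_id: str = "") -> ProteinAssociation:
        """Score one protein from its target sub-matrix M_t."""
        self._check_fitted()
        if M_t.shape[1] != self.n_features_in_:
            raise ValueError(
                f"M_t has {M_t.shape[1]} phenotype columns; background was fitted "
                f"with {self.n_features_in_}"
            )
        ivec = initial_score(M_t, self.sim_threshold, protein_id)
        z = z_transform(ivec, self.background_fit_)
        pz = p_z(z, self.z_pool_)
        o = original_score(z, self.c_)
        po = p_o(o, self.o_pool_)
        return ProteinAssociation(protein_id, ivec.m, ivec.scores, z, pz, o, float(po))

    def score_proteins(
        self, M: SimilarityMatrix, ligand_sets: list[LigandSet]
    ) -> AssociationResult:
        """Run the full two-layer chain for every ligand set against M.

        A protein failing a stage (e.g. ligands missing from M's rows) is
        dropped with a logged reason rather than aborting the run.
        """
        self._check_fitted()
        if not ligand_sets:
            logger.warning("no ligand sets supplied; returning empty result")
        proteins: list[ProteinAssociation] = []
        dropped: list[tuple[str, str]] = []
        for ls in ligand_sets:
            try:
                M_t = slice_target_matrix(M, ls)
                proteins.append(self.score_protein(M_t, ls.protein_id))
            except Exception as exc:  # noqa: BLE001 - protein-level isolation
                logger.warning("dropping protein %s: %s", ls.protein_id, exc)
                dropped.append((ls.protein_id, str(exc)))
        for rank, p in enumerate(sorted(proteins, key=lambda p: (p.p_o, p.protein_id)), 1):
            p.rank = rank
        proteins.sort(key=lambda p: p.rank)
        return AssociationResult(
            col_ids=list(M.col_ids),
            proteins=proteins,
            c=self.c_,
            pz_resolution=self.z_pool_.resolution,
            po_resolution=self.o_pool_.resolution,
            dropped=dropped,
        )


def associate(
    phenotype_actives: list[str] | None,
    ligand_sets: list[LigandSet],
    M: SimilarityMatrix,
    M_r: SimilarityMatrix,
    config: RunConfig,
) -> AssociationResult:
    """Functional entry point for the full chain: fit the background on M_r,
    then score every ligand set against M.

    ``phenotype_actives`` optionally restricts the phenotype columns (by id)
    of both matrices; None uses all columns.
    """
    if phenotype_actives is not None:
        M = _select_columns(M, phenotype_actives)
        M_r = _select_columns(M_r, phenotype_actives)
    model = TwoLayerSEA.from_config(config).fit(M_r)
    return model.score_proteins(M, ligand_sets)


def save_model(model: TwoLayerSEA, path) -> None:
    """Persist a fitted model (background fit, pools, threshold) to an
    .npz archive reusable across association runs."""
    model._check_fitted()
    import json

    np.savez_compressed(
        path,
        params=json.dumps(model.get_params()),
        k_hat=model.background_fit_.k_hat,
        a_hat=model.background_fit_.a_hat,
        b_hat=model.background_fit_.b_hat,
        length_grid=model.background_fit_.length_grid,
        mu_by_length=model.background_fit_.mu_by_length,
        sigma_by_length=model.background_fit_.sigma_by_length,
        z_pool=model.z_pool_.z_values,
        o_pool=model.o_pool_.o_values,
        c=model.c_,
        n_features_in=model.n_features_in_,
        background_cols=np.array(model.background_cols_, dtype=object),
    )


def load_model(path) -> TwoLayerSEA:
    """Restore a fitted model saved by :func:`save_model`."""
    import json

    with np.load(path, allow_pickle=True) as data:
        model = TwoLayerSEA(**json.loads(str(data["params"])))
        model.background_fit_ = BackgroundFit(
            float(data["k_hat"]),
            float(data["a_hat"]),
            float(data["b_hat"]),
            data["length_grid"],
            data["mu_by_length"],
            data["sigma_by_length"],
        )
        model.z_pool_ = ZPool(data["z_pool"])
        model.c_ = float(data["c"])
        model.o_pool_ = OPool(data["o_pool"], model.c_)
        model.n_features_in_ = int(data["n_features_in"])
        model.background_cols_ = [str(c) for c in data["background_cols"]]
    return model


def _select_columns(M: SimilarityMatrix, col_ids: list[str]) -> SimilarityMatrix:
    lookup = {cid: i for i, cid in enumerate(M.col_ids)}
    missing = [c for c in col_ids if c not in lookup]
    if missing:
        raise KeyError(f"phenotype compounds missing from matrix columns: {missing[:5]}")
    idx = [lookup[c] for c in col_ids]
    return SimilarityMatrix(list(M.row_ids), list(col_ids), M.values[:, idx])
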