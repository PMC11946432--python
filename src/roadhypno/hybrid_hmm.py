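"""Hybrid hidden Markov decoder with gradient-boosted discriminative emissions.

The latent driver state (normal vs. road hypnosis) follows a first-order
Markov chain.  Classical HMMs model the emission density ``b_j(o_t)``
generatively; here each state's emission score is produced by a
gradient-boosted tree regressor trained one-vs-rest against the 0/1 state
indicator with a squared-error objective, calibrated to a probability by
Platt scaling on out-of-fold scores, and converted to a scaled likelihood
``p(S_j | o) / p(S_j)`` — the standard bridge from a discriminative
classifier to the forward and Viterbi recursions (dividing by the class
prior leaves path ranking and posteriors identical to using the true
likelihood up to a per-step constant).

A separate linear readout maps a standardized feature row to a continuous
"hypnosis degree"; the shipped default coefficients are the model's
published regression weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import xgboost as xgb
from sklearn.model_selection import StratifiedKFold

from .config import HmmConfig, RunConfig
from .fusion import (FeatureMatrix, SLOT_FEATURES, STATES, concat_matrices,
                     extract_features, standardize)
from .timeline_io import MultimodalRecording

__all__ = [
    "HmmSpec",
    "EmissionModel",
    "DecodeResult",
    "HybridHmm",
    "DEFAULT_COEFFICIENTS",
    "DEFAULT_INTERCEPT",
    "estimate_transitions",
    "train_emissions",
    "emission_likelihood",
    "forward",
    "viterbi",
    "forward_filter",
    "viterbi_path",
    "hypnosis_degree",
    "train",
    "predict",
]

EMISSION_FLOOR = 1e-12

#: published regression weights of the 14-slot hypnosis-degree readout
#: (slots 2, 3, 11, 13 are reserved and carry weight 0)
DEFAULT_COEFFICIENTS = np.array([
    0.231,   # 1  speed
    0.0,     # 2  (reserved)
    0.0,     # 3  (reserved)
    0.078,   # 4  delta
    0.113,   # 5  theta
    0.004,   # 6  alpha
    -0.112,  # 7  beta
    0.074,   # 8  gamma
    -0.007,  # 9  gaze velocity
    0.083,   # 10 pupil diameter left
    0.0,     # 11 (reserved)
    -0.179,  # 12 pupil diameter right
    0.0,     # 13 (reserved)
    0.071,   # 14 inter-pupillary distance
])
DEFAULT_INTERCEPT = 0.471


@dataclass
class HmmSpec:
    """Initial distribution and transition matrix over named states."""

    states: list[str]
    initial: np.ndarray  # (N,)
    transitions: np.ndarray  # (N, N), rows sum to 1

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        n = len(self.states)
        if self.initial.shape != (n,) or self.transitions.shape != (n, n):
            raise ValueError("shape mismatch between states, pi and A")
        if np.any(self.initial < 0) or np.any(self.transitions < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(self.initial.sum() - 1) > 1e-10:
            raise ValueError("initial distribution must sum to 1")
        if np.max(np.abs(self.transitions.sum(axis=1) - 1)) > 1e-10:
            raise ValueError("transition rows must sum to 1")


@dataclass
class EmissionModel:
    """Per-state calibrated boosted-tree scorers.

    ``boosters[j]`` regresses the 0/1 indicator of state ``j``;
    ``platt[j] = (a, b)`` maps its raw score ``s`` to a calibrated
    probability ``sigmoid(a·s + b)``; ``priors`` are the training state
    frequencies used for the scaled-likelihood conversion.
    """

    states: list[str]
    feature_names: list[str]
    boosters: list[xgb.Booster]
    platt: list[tuple[float, float]]
    priors: np.ndarray

    def raw_scores(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {x.shape[1]}")
        dm = xgb.DMatrix(x)
        return np.column_stack([b.predict(dm) for b in self.boosters])

    def posteriors(self, x: np.ndarray) -> np.ndarray:
        """Calibrated, renormalized state posteriors p(S_j | o)."""
        raw = self.raw_scores(x)
        cal = np.empty_like(raw)
        for j, (a, b) in enumerate(self.platt):
            cal[:, j] = _sigmoid(a * raw[:, j] + b)
        cal = np.clip(cal, 1e-15, 1 - 1e-15)
        return cal / cal.sum(axis=1, keepdims=True)


@dataclass
class DecodeResult:
    """Filtered posteriors, likelihood, Viterbi path and degree series."""

    states: list[str]
    times: np.ndarray
    posteriors: np.ndarray  # (T, N) filtered
    scaling: np.ndarray  # (T,) per-step normalizers c_t
    log_likelihood: float
    viterbi: np.ndarray  # (T,) state indices
    viterbi_log_score: float
    hypnosis_degree: np.ndarray | None = None

    @property
    def viterbi_labels(self) -> np.ndarray:
        return np.asarray(self.states, dtype=object)[self.viterbi].astype(str)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(z, dtype=float)))


# ---------------------------------------------------------------------------
# transition estimation


def estimate_transitions(label_sequences: list[np.ndarray],
                         states: list[str] = STATES,
                         kappa: float = 1.0) -> HmmSpec:
    """Supervised transition estimation with additive smoothing.

    ``a_ij = (count(i→j) + κ) / (Σ_k count(i→k) + Nκ)``; the initial
    distribution comes from first-step frequencies with the same smoothing.
    """
    n = len(states)
    index = {s: i for i, s in enumerate(states)}
    counts = np.zeros((n, n))
    firsts = np.zeros(n)
    n_steps = 0
    for seq in label_sequences:
        seq = np.asarray(seq)
        if seq.size == 0:
            continue
        try:
            idx = np.array([index[s] for s in seq])
        except KeyError as exc:
            raise ValueError(f"unknown state label {exc.args[0]!r}") from None
        firsts[idx[0]] += 1
        np.add.at(counts, (idx[:-1], idx[1:]), 1)
        n_steps += max(len(seq) - 1, 0)
    if n_steps < 1:
        raise ValueError("need at least one sequence with >= 2 steps")
    denom = counts.sum(axis=1, keepdims=True) + n * kappa
    with np.errstate(invalid="ignore"):
        a = (counts + kappa) / denom
    a[denom[:, 0] == 0] = 1.0 / n  # states never visited: uniform row
    pi = (firsts + kappa) / (firsts.sum() + n * kappa)
    return HmmSpec(states=list(states), initial=pi, transitions=a)


# ---------------------------------------------------------------------------
# emission training


def _platt_fit(scores: np.ndarray, targets: np.ndarray) -> tuple[float, float]:
    """Fit the sigmoid p = 1/(1+exp(-(a·s+b))) by regularized logistic loss.

    Uses Platt's smoothed targets to avoid saturation on separable data.
    """
    from scipy.optimize import minimize

    s = np.asarray(scores, dtype=float)
    y = np.asarray(targets, dtype=float)
    n_pos, n_neg = y.sum(), len(y) - y.sum()
    t = np.where(y > 0.5, (n_pos + 1) / (n_pos + 2), 1 / (n_neg + 2))

    def nll(params):
        a, b = params
        z = a * s + b
        # stable cross-entropy on smoothed targets
        return float(np.sum(np.logaddexp(0, z) - t * z))

    res = minimize(nll, x0=np.array([1.0, 0.0]), method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    a, b = res.x
    return float(a), float(b)


def _booster_params(cfg: HmmConfig) -> dict:
    return {
        "max_depth": cfg.max_depth,
        "eta": cfg.learning_rate,
        "lambda": cfg.reg_lambda,
        "objective": "reg:squarederror",
        "tree_method": "hist",
        "nthread": 1,
        "seed": cfg.seed,
        "base_score": 0.5,
    }


def _fit_booster(x: np.ndarray, y: np.ndarray, cfg: HmmConfig) -> xgb.Booster:
    return xgb.train(_booster_params(cfg), xgb.DMatrix(x, label=y),
                     num_boost_round=cfg.n_trees)


def train_emissions(matrix: FeatureMatrix, states: list[str] = STATES,
                    config: HmmConfig | None = None) -> EmissionModel:
    """One boosted-tree scorer per state, Platt-calibrated.

    Each scorer regresses the 0/1 indicator of its state under squared
    error (plus the trees' L2 leaf regularization).  Calibration sigmoids
    are fitted on out-of-fold raw scores from an internal stratified K-fold
    so the calibrator never sees in-sample (over-confident) scores.
    """
    cfg = config or HmmConfig()
    if matrix.labels is None:
        raise ValueError("training matrix must carry row labels")
    x = matrix.values
    labels = np.asarray(matrix.labels)
    boosters, platt = [], []
    priors = np.empty(len(states))
    for j, state in enumerate(states):
        y = (labels == state).astype(float)
        n_j = int(y.sum())
        priors[j] = n_j / len(y)
        if n_j < 2 or len(y) - n_j < 2:
            raise ValueError(f"state {state!r} has fewer than 2 examples")
        oof = np.empty(len(y))
        skf = StratifiedKFold(n_splits=cfg.calib_folds, shuffle=True,
                              random_state=cfg.seed)
        for tr, va in skf.split(x, y):
            fold_model = _fit_booster(x[tr], y[tr], cfg)
            oof[va] = fold_model.predict(xgb.DMatrix(x[va]))
        boosters.append(_fit_booster(x, y, cfg))
        platt.append(_platt_fit(oof, y))
    return EmissionModel(
        states=list(states),
        feature_names=matrix.columns,
        boosters=boosters,
        platt=platt,
        priors=priors,
    )


def emission_likelihood(model: EmissionModel, observations: np.ndarray
                        ) -> np.ndarray:
    """Scaled likelihoods ``b̂_j(o) = p(S_j | o) / p(S_j)``, floored > 0."""
    post = model.posteriors(observations)
    return np.maximum(post / model.priors, EMISSION_FLOOR)


# ---------------------------------------------------------------------------
# decoding primitives (operate on a precomputed emission table)


def forward_filter(pi: np.ndarray, a: np.ndarray, emissions: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, float]:
    """Scaled forward recursion.

    Returns ``(posteriors, scaling, log_likelihood)`` where ``posteriors``
    rows are the filtered state distributions and
    ``log_likelihood = Σ log c_t``.
    """
    emissions = np.atleast_2d(np.asarray(emissions, dtype=float))
    t_len, n = emissions.shape
    alpha = np.empty((t_len, n))
    scaling = np.empty(t_len)
    vec = np.asarray(pi, dtype=float) * emissions[0]
    for t in range(t_len):
        if t > 0:
            vec = (alpha[t - 1] @ a) * emissions[t]
        c = vec.sum()
        if not c > 0:
            raise ValueError(f"all-zero emission row at step {t}")
        alpha[t] = vec / c
        scaling[t] = c
    return alpha, scaling, float(np.sum(np.log(scaling)))


def viterbi_path(pi: np.ndarray, a: np.ndarray, emissions: np.ndarray
                 ) -> tuple[np.ndarray, float]:
    """Max-product decoding in log space; ties break to the lower index."""
    emissions = np.atleast_2d(np.asarray(emissions, dtype=float))
    t_len, n = emissions.shape
    with np.errstate(divide="ignore"):
        log_a = np.log(np.asarray(a, dtype=float))
        log_e = np.log(emissions)
        log_pi = np.log(np.asarray(pi, dtype=float))
    delta = log_pi + log_e[0]
    back = np.zeros((t_len, n), dtype=int)
    for t in range(1, t_len):
        cand = delta[:, None] + log_a  # cand[i, j]
        back[t] = np.argmax(cand, axis=0)  # argmax takes the lowest index on ties
        delta = cand[back[t], np.arange(n)] + log_e[t]
    path = np.empty(t_len, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(t_len - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path, float(delta[path[-1]])


def forward(spec: HmmSpec, model: EmissionModel, observations: np.ndarray,
            times: np.ndarray | None = None) -> DecodeResult:
    """Filtered posteriors and log-likelihood for an observation sequence."""
    emis = emission_likelihood(model, observations)
    post, scaling, ll = forward_filter(spec.initial, spec.transitions, emis)
    path, score = viterbi_path(spec.initial, spec.transitions, emis)
    t = np.arange(len(post)) if times is None else np.asarray(times)
    return DecodeResult(states=list(spec.states), times=t, posteriors=post,
                        scaling=scaling, log_likelihood=ll, viterbi=path,
                        viterbi_log_score=score)


def viterbi(spec: HmmSpec, model: EmissionModel,
            observations: np.ndarray) -> np.ndarray:
    """Most probable state path for an observation sequence."""
    emis = emission_likelihood(model, observations)
    path, _ = viterbi_path(spec.initial, spec.transitions, emis)
    return path


# ---------------------------------------------------------------------------
# hypnosis-degree readout


def hypnosis_degree(row: np.ndarray,
                    coefficients: np.ndarray = DEFAULT_COEFFICIENTS,
                    intercept: float = DEFAULT_INTERCEPT) -> float | np.ndarray:
    """Linear readout ``Σ x_i β_i + β_0`` on the 14-slot standardized row.

    Accepts a single 14-vector or a ``(T, 14)`` matrix.
    """
    x = np.asarray(row, dtype=float)
    coefficients = np.asarray(coefficients, dtype=float)
    if x.shape[-1] != coefficients.shape[0]:
        raise ValueError(
            f"expected {coefficients.shape[0]} slots, got {x.shape[-1]}")
    out = x @ coefficients + intercept
    return float(out) if out.ndim == 0 else out


def fit_degree_coefficients(matrix: FeatureMatrix) -> tuple[np.ndarray, float]:
    """Refit the readout by least squares of the 0/1 label on the 14 slots.

    Alternative to the shipped default weights; padding slots stay exactly 0
    because their columns are identically zero (minimum-norm solution).
    """
    if matrix.labels is None:
        raise ValueError("matrix must carry labels")
    slots = matrix.to_slots()
    y = (np.asarray(matrix.labels) == STATES[1]).astype(float)
    design = np.column_stack([slots, np.ones(len(y))])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return beta[:-1], float(beta[-1])


# ---------------------------------------------------------------------------
# end-to-end bundle


@dataclass
class HybridHmm:
    """Trained bundle: chain spec, emission model, fusion moments, readout."""

    spec: HmmSpec
    emissions: EmissionModel
    fusion_mean: dict[str, float]
    fusion_std: dict[str, float]
    coefficients: np.ndarray = field(
        default_factory=lambda: DEFAULT_COEFFICIENTS.copy())
    intercept: float = DEFAULT_INTERCEPT
    config: RunConfig = field(default_factory=RunConfig)

    # -- persistence ------------------------------------------------------
    def save(self, bundle_dir: Path | str) -> Path:
        d = Path(bundle_dir)
        (d / "emissions").mkdir(parents=True, exist_ok=True)
        (d / "hmm.json").write_text(json.dumps({
            "states": self.spec.states,
            "initial": self.spec.initial.tolist(),
            "transitions": self.spec.transitions.tolist(),
        }, indent=2))
        (d / "fusion_params.json").write_text(json.dumps({
            "feature_names": self.emissions.feature_names,
            "mean": self.fusion_mean,
            "std": self.fusion_std,
        }, indent=2))
        (d / "coefficients.json").write_text(json.dumps({
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
        }, indent=2))
        (d / "emissions" / "platt.json").write_text(json.dumps({
            "platt": self.emissions.platt,
            "priors": self.emissions.priors.tolist(),
        }, indent=2))
        for j, booster in enumerate(self.emissions.boosters):
            booster.save_model(str(d / "emissions" / f"state_{j}.json"))
        (d / "config.json").write_text(json.dumps(self.config.to_dict(), indent=2))
        return d

    @classmethod
    def load(cls, bundle_dir: Path | str) -> "HybridHmm":
        d = Path(bundle_dir)
        hmm = json.loads((d / "hmm.json").read_text())
        fus = json.loads((d / "fusion_params.json").read_text())
        coef = json.loads((d / "coefficients.json").read_text())
        cal = json.loads((d / "emissions" / "platt.json").read_text())
        cfg = RunConfig.from_dict(json.loads((d / "config.json").read_text()))
        boosters = []
        for j in range(len(hmm["states"])):
            b = xgb.Booster()
            b.load_model(str(d / "emissions" / f"state_{j}.json"))
            boosters.append(b)
        spec = HmmSpec(states=hmm["states"], initial=hmm["initial"],
                       transitions=hmm["transitions"])
        emissions = EmissionModel(
            states=hmm["states"],
            feature_names=fus["feature_names"],
            boosters=boosters,
            platt=[tuple(p) for p in cal["platt"]],
            priors=np.asarray(cal["priors"]),
        )
        return cls(spec=spec, emissions=emissions, fusion_mean=fus["mean"],
                   fusion_std=fus["std"],
                   coefficients=np.asarray(coef["coefficients"]),
                   intercept=coef["intercept"], config=cfg)


def train(recordings: list[MultimodalRecording],
          config: RunConfig | None = None,
          refit_degree: bool = False) -> HybridHmm:
    """Fit the full pipeline on labelled recordings.

    Extract + fuse each recording, estimate standardization moments and
    transitions from the pooled training rows, train and calibrate the
    per-state emission scorers.
    """
    cfg = config or RunConfig()
    matrices = [extract_features(r, cfg) for r in recordings]
    return train_from_matrices(matrices, cfg, refit_degree=refit_degree)


def train_from_matrices(matrices: list[FeatureMatrix],
                        config: RunConfig | None = None,
                        refit_degree: bool = False) -> HybridHmm:
    """Fit transitions + emissions from already fused, labelled matrices."""
    cfg = config or RunConfig()
    pooled = concat_matrices(matrices)
    if pooled.labels is None or STATES[1] not in set(pooled.labels):
        raise ValueError("training data contain no hypnosis labels")
    pooled_std = standardize(pooled)
    spec = estimate_transitions([m.labels for m in matrices],
                                states=STATES, kappa=cfg.hmm.kappa)
    emissions = train_emissions(pooled_std, states=STATES, config=cfg.hmm)
    bundle = HybridHmm(spec=spec, emissions=emissions,
                       fusion_mean=pooled_std.mean, fusion_std=pooled_std.std,
                       config=cfg)
    if refit_degree:
        bundle.coefficients, bundle.intercept = fit_degree_coefficients(pooled_std)
    return bundle


def predict(recording_or_matrix, bundle: HybridHmm) -> DecodeResult:
    """Decode one recording (or pre-fused matrix) with a trained bundle.

    Runs fusion with the training standardization moments, then the scaled
    forward recursion and Viterbi decoding, and evaluates the linear
    hypnosis-degree readout on every standardized row.
    """
    if isinstance(recording_or_matrix, MultimodalRecording):
        matrix = extract_features(recording_or_matrix, bundle.config)
    else:
        matrix = recording_or_matrix
    missing = [c for c in bundle.emissions.feature_names if c not in matrix.columns]
    if missing:
        raise ValueError(f"missing feature column(s): {missing}")
    matrix_std = standardize(matrix, params=(bundle.fusion_mean, bundle.fusion_std))
    x = matrix_std.data[bundle.emissions.feature_names].to_numpy(dtype=float)
    result = forward(bundle.spec, bundle.emissions, x, times=matrix_std.times)
    result.hypnosis_degree = hypnosis_degree(
        matrix_std.to_slots(), bundle.coefficients, bundle.intercept)
    return result
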