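"""Denoising-autoencoder ensemble detection of correlation-break markers.

A metabolite can be pathological without any shift in its own concentration:
what breaks is its *relationship* to the rest of the profile.  To find such
metabolites, a bottlenecked denoising autoencoder is trained on control
profiles only — it learns the inter-metabolite dependence structure of the
healthy group, because the bottleneck forces reconstruction through shared
structure rather than memorization.  Applied to clean (noise-free) case
profiles, metabolites whose control-learned relationships are disrupted
reconstruct poorly.  Per metabolite, the case and control reconstruction
error distributions are compared with the Mann-Whitney test under
Benjamini-Hochberg FDR control; because a single architecture is somewhat
arbitrary, an ensemble of models differing in bottleneck width votes, and
metabolites flagged by nearly all models form the secondary-marker set.

Noise model during training: each metabolite value CO receives CN = CO + d*e
with e ~ N(0, sigma=CO), i.e. the corruption is proportional to the value
itself; the network sees the noisy profile and must output the clean one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._train import adam_train
from .io_prep import MetabolomicMatrix, apply_scaler, fit_scaler
from .screening import adjust_benjamini_hochberg, mann_whitney

logger = logging.getLogger(__name__)


@dataclass
class NoiseModel:
    """Multiplicative-scale Gaussian corruption: CN = CO + d * N(0, CO)."""

    d: float = 0.25
    replicates_per_profile: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("noise level d must be >= 0")
        if self.replicates_per_profile < 1:
            raise ValueError("replicates_per_profile must be >= 1")


def add_noise(
    profile: np.ndarray, nm: NoiseModel, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Generate noisy replicates of one profile.

    Each replicate perturbs metabolite n as ``CO_n + d * e`` with
    ``e ~ N(0, sigma=CO_n)``, so the noise SD is ``d * CO_n`` — zero values
    stay exactly zero.  Returns an array of shape
    ``(replicates_per_profile, n_metabolites)``.
    """
    profile = np.asarray(profile, dtype=float)
    if not np.all(np.isfinite(profile)):
        raise ValueError("profile must be finite")
    rng = rng if rng is not None else np.random.default_rng(nm.seed)
    e = rng.standard_normal((nm.replicates_per_profile, profile.size)) * np.abs(profile)
    return profile + nm.d * e


@dataclass
class DAEConfig:
    """Architecture and training settings for one autoencoder.

    Three fully connected layers (``n_features -> hidden_size -> n_features``)
    with rectifier activations on the hidden *and* output layer — hence the
    [0, 1] input scaling.  Trained with Adam on mean squared error between
    the clean profile and the reconstruction of its noisy replicate.
    """

    n_features: int
    hidden_size: int
    epochs: int = 20
    batch_size: int = 8
    learning_rate: float = 0.001
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.hidden_size < self.n_features:
            raise ValueError("hidden_size must satisfy 0 < hidden < n_features")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


class ReluAutoencoder:
    """Minimal dense autoencoder: ReLU hidden and output layers."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        # He initialization, matched to the rectifier activations
        self.W1 = rng.standard_normal((n_in, n_hidden)) * np.sqrt(2.0 / n_in)
        self.b1 = np.zeros(n_hidden)
        self.W2 = rng.standard_normal((n_hidden, n_in)) * np.sqrt(2.0 / n_hidden)
        self.b2 = np.zeros(n_in)

    def predict(self, x: np.ndarray) -> np.ndarray:
        h = np.maximum(x @ self.W1 + self.b1, 0.0)
        return np.maximum(h @ self.W2 + self.b2, 0.0)


@dataclass
class TrainedDAE:
    net: ReluAutoencoder
    config: DAEConfig
    train_loss: float
    test_loss: float


def train_dae(
    control_profiles: np.ndarray, cfg: DAEConfig, nm: NoiseModel
) -> TrainedDAE:
    """Train one denoising autoencoder on scaled control profiles.

    Control samples are split into train/monitor sets by ``train_fraction``;
    each training sample spawns ``nm.replicates_per_profile`` noisy copies
    whose reconstruction target is the clean profile.  The epoch count is
    fixed (no early stopping); the monitor loss is reported only.
    Deterministic for a given ``cfg.seed``.
    """
    X = np.asarray(control_profiles, dtype=float)
    if X.ndim != 2 or X.shape[1] != cfg.n_features:
        raise ValueError(f"expected (n, {cfg.n_features}) control matrix")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 control samples")
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(X.shape[0])
    n_train = max(1, int(round(cfg.train_fraction * X.shape[0])))
    n_train = min(n_train, X.shape[0] - 1) if X.shape[0] > 1 else n_train
    train_idx, test_idx = order[:n_train], order[n_train:]

    reps = nm.replicates_per_profile
    noisy = np.vstack([add_noise(X[i], nm, rng) for i in train_idx])
    clean = np.repeat(X[train_idx], reps, axis=0)

    net = ReluAutoencoder(cfg.n_features, cfg.hidden_size, rng)
    # start the rectified output layer at the target means so no output unit
    # is born dead (pre-activation <= 0 for every input blocks its gradient)
    net.b2 = clean.mean(axis=0).copy()
    n_obs = noisy.shape[0]
    perms = np.vstack([rng.permutation(n_obs) for _ in range(cfg.epochs)])
    # the kernel wants both weight matrices laid out with contiguous rows
    W1r = np.ascontiguousarray(net.W1.T)
    W2r = np.ascontiguousarray(net.W2.T)
    last_epoch_loss = float(
        adam_train(
            W1r, net.b1, W2r, net.b2,
            np.ascontiguousarray(noisy), np.ascontiguousarray(clean),
            perms, cfg.batch_size, cfg.learning_rate,
        )
    )
    net.W1 = np.ascontiguousarray(W1r.T)
    net.W2 = np.ascontiguousarray(W2r.T)
    test_X = X[test_idx] if test_idx.size else X[train_idx]
    test_loss = float(np.mean((net.predict(test_X) - test_X) ** 2))
    logger.debug(
        "hidden=%d train_loss=%.5f test_loss=%.5f",
        cfg.hidden_size, last_epoch_loss, test_loss,
    )
    return TrainedDAE(net, cfg, last_epoch_loss, test_loss)


def reconstruction_errors(model: TrainedDAE, profiles: np.ndarray) -> np.ndarray:
    """Per-sample, per-metabolite |input - output| on CLEAN (noise-free) inputs."""
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.config.n_features:
        raise ValueError(
            f"expected {model.config.n_features} features, got {X.shape}"
        )
    return np.abs(X - model.net.predict(X))


def detect_anomalies(
    case_errors: np.ndarray,
    control_errors: np.ndarray,
    fdr_alpha: float = 0.05,
    metabolite_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-metabolite two-sided Mann-Whitney on error distributions, BH-corrected.

    Returns a frame with columns ``p``, ``p_adj`` and ``flag``
    (``p_adj`` < ``fdr_alpha``), one row per metabolite.
    """
    case_errors = np.asarray(case_errors, dtype=float)
    control_errors = np.asarray(control_errors, dtype=float)
    if case_errors.shape[1] != control_errors.shape[1]:
        raise ValueError("error tables must share the metabolite dimension")
    n_met = case_errors.shape[1]
    pvals = np.array(
        [mann_whitney(case_errors[:, j], control_errors[:, j])[1] for j in range(n_met)]
    )
    p_adj = adjust_benjamini_hochberg(pvals)
    index = metabolite_ids if metabolite_ids is not None else list(range(n_met))
    return pd.DataFrame(
        {"p": pvals, "p_adj": p_adj, "flag": p_adj < fdr_alpha},
        index=pd.Index(index, name="metabolite"),
    )


def spread_hidden_sizes(
    n_features: int, n_models: int, lo_frac: float = 50 / 210, hi_frac: float = 149 / 210
) -> list[int]:
    """Bottleneck widths spread evenly over the fraction band of the feature count.

    For the study shape (210 features, 100 models) this is exactly the
    integer range 50..149; for other feature counts the band scales
    proportionally.
    """
    lo = max(1, int(round(lo_frac * n_features)))
    hi = min(n_features - 1, int(round(hi_frac * n_features)))
    return [int(round(h)) for h in np.linspace(lo, hi, n_models)]


@dataclass
class EnsembleConfig:
    """Ensemble-of-architectures settings.

    ``hidden_sizes`` gives one bottleneck width per model (default: the
    50..149 band scaled to the feature count); ``consensus_min`` is the
    number of models that must flag a metabolite for it to enter the
    secondary-marker set (study value: 97 of 100).
    """

    n_models: int = 100
    hidden_sizes: list[int] | None = None
    fdr_alpha: float = 0.05
    consensus_min: int = 97
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_sizes is not None and len(self.hidden_sizes) != self.n_models:
            raise ValueError("hidden_sizes must list one width per model")
        if self.consensus_min > self.n_models:
            raise ValueError("consensus_min cannot exceed n_models")


@dataclass
class EnsembleResult:
    """Consensus table plus per-model detail.

    ``table`` has one row per metabolite, sorted by descending consensus:
    ``consensus_count`` (models flagging it), ``median_p_adj`` across models,
    and ``selected`` (count >= ``consensus_min``).  ``flags``/``p_adj`` are
    (models x metabolites) arrays in matrix column order.
    """

    table: pd.DataFrame
    flags: np.ndarray = field(repr=False, default=None)
    p_adj: np.ndarray = field(repr=False, default=None)

    @property
    def selected(self) -> set[str]:
        return set(self.table.index[self.table["selected"]])


def run_ensemble(
    m: MetabolomicMatrix,
    ens: EnsembleConfig | None = None,
    dae_template: DAEConfig | None = None,
    nm: NoiseModel | None = None,
    holdout_controls_only: bool = False,
) -> EnsembleResult:
    """Train the autoencoder ensemble and build the consensus marker table.

    The matrix must be preprocessed (imputed, log-transformed); scaling to
    [0, 1] is fitted on the control group here.  Each model gets its own
    bottleneck width and derived seed.  Control-group errors are computed on
    all control samples by default (``holdout_controls_only`` restricts them
    to the samples held out of that model's training split).
    """
    ens = ens or EnsembleConfig()
    nm = nm or NoiseModel()
    if np.isnan(m.values).any():
        raise ValueError("ensemble requires an imputed matrix")
    hidden = ens.hidden_sizes or spread_hidden_sizes(m.n_metabolites, ens.n_models)
    controls = m.controls()
    cases = m.cases()
    if controls.n_samples < 2 or cases.n_samples < 1:
        raise ValueError("need >=2 control and >=1 case samples")
    scaler = fit_scaler(controls)
    Xc = apply_scaler(scaler, controls).values
    Xa = apply_scaler(scaler, cases).values

    n_met = m.n_metabolites
    flags = np.zeros((ens.n_models, n_met), dtype=bool)
    p_adj = np.ones((ens.n_models, n_met))
    seeds = np.random.SeedSequence(ens.seed).spawn(ens.n_models)
    for i, (h, ss) in enumerate(zip(hidden, seeds)):
        seed_i = int(ss.generate_state(1)[0] % (2**31))
        cfg = DAEConfig(
            n_features=n_met,
            hidden_size=h,
            epochs=dae_template.epochs if dae_template else 20,
            batch_size=dae_template.batch_size if dae_template else 8,
            learning_rate=dae_template.learning_rate if dae_template else 0.001,
            train_fraction=dae_template.train_fraction if dae_template else 0.8,
            seed=seed_i,
        )
        model = train_dae(Xc, cfg, nm)
        ctrl_X = Xc
        if holdout_controls_only:
            rng = np.random.default_rng(seed_i)
            order = rng.permutation(Xc.shape[0])
            n_train = max(1, int(round(cfg.train_fraction * Xc.shape[0])))
            n_train = min(n_train, Xc.shape[0] - 1)
            ctrl_X = Xc[order[n_train:]]
        res = detect_anomalies(
            reconstruction_errors(model, Xa),
            reconstruction_errors(model, ctrl_X),
            ens.fdr_alpha,
        )
        flags[i] = res["flag"].to_numpy()
        p_adj[i] = res["p_adj"].to_numpy()
        logger.debug("model %d/%d (hidden=%d): %d flags", i + 1, ens.n_models, h, flags[i].sum())

    counts = flags.sum(axis=0)
    table = pd.DataFrame(
        {
            "consensus_count": counts,
            "median_p_adj": np.median(p_adj, axis=0),
            "selected": counts >= ens.consensus_min,
        },
        index=pd.Index(m.metabolite_ids, name="metabolite"),
    ).sort_values(["consensus_count", "median_p_adj"], ascending=[False, True])
    return EnsembleResult(table=table, flags=flags, p_adj=p_adj)
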