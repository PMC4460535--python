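"""Neural-network sensitivity analysis and sensitivity-ranked RFE.

For a one-hidden-layer net the Jacobian of outputs with respect to inputs
has the closed form

    S(x) = diag(o'_1..o'_K) . W . diag(y'_1..y'_J) . V

with the activation derivatives evaluated on the forward pass at x.  The
entry S_ki quantifies how much voxel i contributes, incrementally, to the
decision for class k at that input.  Because net training is stochastic,
S is averaged over an ensemble of independently trained nets (100 for
final maps), then RMS-averaged over all input vectors, and the per-voxel
relevance is phi_i = max_k S_RMS[k, i].

Recursive feature elimination uses phi as the ranking criterion: features
below a fixed sensitivity threshold are removed each iteration (at least
one per iteration to guarantee progress), the decoder is re-estimated,
and iteration stops when the bootstrapped accuracy falls significantly
(p = 0.05, one-sided bootstrap comparison) below the running peak.
Sensitivities are computed and reported in standardized-input space so
phi is comparable across voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import ExampleSet
from .evaluate import bootstrap_ci, cross_validate
from .nnet import ACTIVATIONS, TrainedNet, train_nn

__all__ = ["SensitivityResult", "RfeTrajectory", "sensitivity_matrix",
           "aggregate_sensitivity", "train_ensemble", "rfe",
           "DEFAULT_N_NETS_MAP", "DEFAULT_N_NETS_RFE"]

#: ensemble sizes: final maps average 100 nets; RFE iterations use fewer
DEFAULT_N_NETS_MAP = 100
DEFAULT_N_NETS_RFE = 20


@dataclass
class SensitivityResult:
    S_rms: np.ndarray       # (K, I), nonnegative
    phi: np.ndarray         # (I,), per-voxel max over classes
    n_nets: int
    n_inputs_used: int


@dataclass
class RfeTrajectory:
    fraction_remaining: list[float] = field(default_factory=list)
    mean_accuracy: list[float] = field(default_factory=list)
    ci_lo: list[float] = field(default_factory=list)
    ci_hi: list[float] = field(default_factory=list)
    surviving_indices: list[np.ndarray] = field(default_factory=list)
    stopped_reason: str = ""

    def append(self, frac, acc, lo, hi, surviving):
        self.fraction_remaining.append(float(frac))
        self.mean_accuracy.append(float(acc))
        self.ci_lo.append(float(lo))
        self.ci_hi.append(float(hi))
        self.surviving_indices.append(np.asarray(surviving))

    @property
    def peak_iteration(self) -> int:
        return int(np.argmax(self.mean_accuracy))


def sensitivity_matrix(net: TrainedNet, x: np.ndarray) -> np.ndarray:
    """K x I Jacobian of the net's outputs with respect to standardized
    inputs, evaluated at raw-space example x."""
    x = np.asarray(x, dtype=float).ravel()
    if len(x) != net.n_inputs:
        raise ValueError("example length does not match the net")
    z = net.standardize(x)
    Y, O = net.forward(z)
    if not (np.all(np.isfinite(Y)) and np.all(np.isfinite(O))):
        raise FloatingPointError("non-finite forward pass")
    d_h = ACTIVATIONS[net.hidden_activation][1]
    d_o = ACTIVATIONS[net.output_activation][1]
    o_prime = d_o(O).ravel()            # (K,)
    y_prime = d_h(Y).ravel()            # (J,)
    return (o_prime[:, None] * net.W) @ (y_prime[:, None] * net.V)


def aggregate_sensitivity(nets: list[TrainedNet], X: np.ndarray) -> SensitivityResult:
    """Ensemble-averaged, RMS-over-inputs sensitivity.

    S_avg(x) = mean over nets of S(x); S_RMS = sqrt(mean_n S_avg(x_n)^2)
    entrywise over the N rows of X; phi_i = max_k S_RMS[k, i].
    """
    if not nets:
        raise ValueError("need at least one net")
    I, K = nets[0].n_inputs, nets[0].n_outputs
    co = nets[0].class_order
    for net in nets:
        if net.n_inputs != I or net.n_outputs != K or \
                not np.array_equal(net.class_order, co):
            raise ValueError("nets must share input/output shape and class order")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    acc = np.zeros((K, I))
    for x in X:
        S_avg = np.zeros((K, I))
        for net in nets:
            S_avg += sensitivity_matrix(net, x)
        S_avg /= len(nets)
        acc += S_avg ** 2
    S_rms = np.sqrt(acc / X.shape[0])
    return SensitivityResult(S_rms=S_rms, phi=S_rms.max(axis=0),
                             n_nets=len(nets), n_inputs_used=X.shape[0])


def train_ensemble(trainset: ExampleSet, n_nets: int, seed: int = 0,
                   **train_kw) -> list[TrainedNet]:
    """Train n_nets independent nets (distinct seed substreams)."""
    seeds = np.random.SeedSequence(seed).generate_state(n_nets) % (2 ** 31)
    return [train_nn(trainset, seed=int(s), **train_kw) for s in seeds]


def rfe(examples: ExampleSet, threshold: float | None = None,
        cv_args: dict | None = None, max_iter: int = 50, seed: int = 0,
        n_nets: int = DEFAULT_N_NETS_RFE, n_boot: int = 500,
        alpha: float = 0.05, train_kw: dict | None = None) -> RfeTrajectory:
    """Sensitivity-ranked recursive feature elimination.

    Each iteration trains an ensemble on the surviving features, computes
    phi, removes every feature with phi strictly below ``threshold`` (the
    single lowest-phi feature when none fall below, so progress is
    guaranteed), and re-estimates accuracy by cross-validation with a
    percentile-bootstrap CI over per-decision correctness.  ``threshold``
    defaults to the 10th percentile of the initial phi distribution.
    Iteration stops when a one-sided bootstrap comparison (over fold
    accuracies) puts the current accuracy significantly (p < alpha) below
    the running peak on two consecutive iterations — a single significant
    dip can be a training fluke, so it must persist — when one feature
    remains, or at ``max_iter``.
    """
    if threshold is not None and threshold < 0:
        raise ValueError("threshold must be nonnegative")
    cv_args = dict(cv_args or {})
    cv_args.setdefault("split_unit", "block")
    cv_args.setdefault("classifier_spec", {"name": "nn"})
    train_kw = dict(train_kw or {})
    # keep the ensemble's net settings consistent with the CV classifier
    if isinstance(cv_args.get("classifier_spec"), dict) and \
            cv_args["classifier_spec"].get("name") == "nn":
        for key, val in cv_args["classifier_spec"].items():
            if key != "name":
                train_kw.setdefault(key, val)
    rng = np.random.default_rng(seed)

    traj = RfeTrajectory()
    surviving = np.arange(examples.n_features)
    char_rows = np.flatnonzero(np.asarray(examples.y) != 0)
    peak_draws = None
    peak_mean = -np.inf
    n_signif = 0
    # one fold assignment for the whole elimination path: successive
    # accuracy estimates are then paired, so iteration-to-iteration change
    # reflects the feature set, not fold redraws
    cv_seed = int(rng.integers(2 ** 31))

    for _ in range(max_iter):
        sub = examples.subset_features(surviving)
        nets = train_ensemble(sub, n_nets, seed=int(rng.integers(2 ** 31)),
                              **train_kw)
        phi = aggregate_sensitivity(nets, sub.X[char_rows]).phi
        if threshold is None:
            threshold = float(np.percentile(phi, 10.0))

        res = cross_validate(sub, seed=cv_seed, **cv_args)
        # bootstrap over fold accuracies: the fold is the replication unit
        # of the CV estimate (per-decision resampling would ignore the
        # fold-assignment variance and make the stop rule trigger-happy)
        accs = res.fold_accuracies
        bs_seed = int(rng.integers(2 ** 31))
        lo, hi = bootstrap_ci(accs, level=0.68, n_boot=n_boot, seed=bs_seed)
        draws_rng = np.random.default_rng(bs_seed)
        idx = draws_rng.integers(0, len(accs), size=(n_boot, len(accs)))
        draws = accs[idx].mean(axis=1)
        traj.append(len(surviving) / examples.n_features,
                    res.mean_accuracy, lo, hi, surviving)

        if res.mean_accuracy > peak_mean:
            peak_mean, peak_draws = res.mean_accuracy, draws
            n_signif = 0
        else:
            # one-sided bootstrap comparison: P(current >= peak)
            p = float(np.mean(draws[:, None] >= peak_draws[None, :]))
            n_signif = n_signif + 1 if p < alpha else 0
            if n_signif >= 2:
                traj.stopped_reason = "significant drop below peak"
                break
        if len(surviving) <= 1:
            traj.stopped_reason = "single feature remaining"
            break
        below = np.flatnonzero(phi < threshold)
        drop = below if len(below) else np.array([int(np.argmin(phi))])
        keep = np.setdiff1d(np.arange(len(surviving)), drop)
        if len(keep) == 0:     # never remove everything at once
            keep = np.array([int(np.argmax(phi))])
        surviving = surviving[keep]
    else:
        traj.stopped_reason = "max_iter reached"
    if not traj.stopped_reason:
        traj.stopped_reason = "max_iter reached"
    return traj
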