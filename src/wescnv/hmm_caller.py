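"""Hidden Markov model segmentation of log2 ratio profiles into CNV calls.

Model
-----
Hidden states are integer copy numbers (default 0–4).  A target with copy
number ``c`` emits its log2 patient/reference ratio from a Gaussian centred
at ``log2(c / 2)`` — i.e. −1 for a hemizygous loss, 0 for diploid, +0.585
for a single-copy gain, +1 for ``c = 4``.  Copy number 0 would put the mean
at −inf; a residual-coverage floor of 0.05 (mean ``log2(0.05) ≈ −4.32``)
models the off-target and mismapped reads that keep homozygous deletions
from reading exactly zero.  All states share one emission variance.

Transitions are distance-independent: probability ``stay_prob`` (default
0.99) of keeping the current copy number at each step along the target
grid, with the remaining mass split uniformly over the other states.  The
initial distribution puts 0.9 on diploid.  Chromosomes are independent
chains, each re-initialized from the initial distribution; masked targets
are spliced out, so the chain connects consecutive unmasked targets.

Estimation
----------
:func:`em_fit` re-estimates only the shared variance and a single additive
offset applied to every state mean (a baseline shift absorbing residual
normalization error).  The copy-number spacing of the means is held fixed —
it is dictated by the ``log2(c/2)`` physics, not the data.  EM guarantees a
non-decreasing log-likelihood.

Calling and scoring
-------------------
The Viterbi path is decoded per chromosome; maximal runs of one non-diploid
state with at least ``min_targets`` member targets become calls.  Each call
gets a reliability score: 100 × the mean forward–backward posterior
probability of its copy-number state over its member targets, so the score
lives on a 0–100 scale and calls are kept when score > threshold (default
80, strict).

Implementation notes: forward–backward and Viterbi run batched over all
chromosome chains at once, padded to the longest chain with unit-emission
steps.  Because the transition matrix is row-stochastic, padded steps leave
the scaled alpha/beta recursions and the log-likelihood of real steps
exactly unchanged, so padding is free of numerical side effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml

from .errors import (
    EmptyProfileError,
    NumericalError,
    ParameterError,
    ValidationError,
)
from .normalization import RatioProfile, ReferenceProfile, make_observations
from .targets_io import SampleCounts, TargetGrid

__all__ = [
    "HMMModel",
    "PosteriorMatrix",
    "CNVCall",
    "CallerConfig",
    "init_model",
    "forward_backward",
    "viterbi",
    "em_fit",
    "decode_to_segments",
    "score_call",
    "filter_calls",
    "call_sample",
]

VARIANCE_FLOOR = 1e-4
DELETION_FLOOR = 0.05


@dataclass
class HMMModel:
    """Copy-number HMM: Gaussian emissions, uniform off-diagonal transitions."""

    copy_numbers: tuple[int, ...]
    means: np.ndarray
    variance: float
    stay_prob: float
    initial: np.ndarray
    em_history: list | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        k = len(self.copy_numbers)
        if self.means.shape != (k,) or self.initial.shape != (k,):
            raise ValidationError("means/initial length must match the state count")
        if not np.all(np.diff(self.means) > 0):
            raise ValidationError("state means must increase strictly with copy number")
        if not 0.0 < self.stay_prob < 1.0:
            raise ParameterError(f"stay_prob {self.stay_prob} outside (0, 1)")
        if abs(self.initial.sum() - 1.0) > 1e-8 or np.any(self.initial < 0):
            raise ValidationError("initial distribution must be a probability vector")
        if self.variance < VARIANCE_FLOOR:
            self.variance = VARIANCE_FLOOR

    @property
    def n_states(self) -> int:
        return len(self.copy_numbers)

    @property
    def transition(self) -> np.ndarray:
        k = self.n_states
        if k == 1:
            return np.ones((1, 1))
        a = np.full((k, k), (1.0 - self.stay_prob) / (k - 1))
        np.fill_diagonal(a, self.stay_prob)
        return a


@dataclass
class PosteriorMatrix:
    """Forward–backward output: per-target state posteriors and log-likelihood.

    ``gamma`` has one row per grid target (NaN rows at masked targets); rows
    at unmasked targets sum to 1.
    """

    gamma: np.ndarray
    loglik: float
    copy_numbers: tuple[int, ...]


@dataclass
class CNVCall:
    """One scored copy-number segment in one sample (never copy number 2)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    copy_number: int
    score: float = 0.0
    first_target: int | None = None
    last_target: int | None = None
    n_targets: int | None = None
    share_count: int = 1
    known_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.copy_number == 2:
            raise ValidationError("a CNV call cannot have copy number 2")
        if self.end < self.start:
            raise ValidationError(
                f"call {self.chrom}:{self.start}-{self.end}: end < start"
            )

    @property
    def gain_loss(self) -> str:
        return "gain" if self.copy_number > 2 else "loss"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def init_model(
    expected_variance: float = 0.25,
    copy_numbers: Sequence[int] = (0, 1, 2, 3, 4),
    stay_prob: float = 0.99,
    diploid_initial: float = 0.9,
) -> HMMModel:
    """Default copy-number HMM with means at log2(c/2) and a cn-0 floor."""
    cn = tuple(int(c) for c in copy_numbers)
    if 2 not in cn:
        raise ValidationError("the state set must include the diploid state (2)")
    means = np.array(
        [math.log2(DELETION_FLOOR) if c == 0 else math.log2(c / 2.0) for c in cn]
    )
    k = len(cn)
    initial = np.full(k, (1.0 - diploid_initial) / (k - 1)) if k > 1 else np.ones(1)
    initial[cn.index(2)] = diploid_initial if k > 1 else 1.0
    return HMMModel(
        copy_numbers=cn,
        means=means,
        variance=float(expected_variance),
        stay_prob=stay_prob,
        initial=initial,
    )


# ---------------------------------------------------------------------------
# chain packing


def _chains(obs: RatioProfile) -> list[np.ndarray]:
    """Ordinal indices of unmasked targets, one array per chromosome chain."""
    unmasked = ~obs.mask
    chains: list[np.ndarray] = []
    if obs.grid is not None:
        for _, lo, hi in obs.grid.chrom_ranges():
            idx = np.arange(lo, hi)[unmasked[lo:hi]]
            if idx.size:
                chains.append(idx)
    else:
        idx = np.nonzero(unmasked)[0]
        if idx.size:
            chains.append(idx)
    if not chains:
        raise EmptyProfileError("no unmasked targets to decode")
    return chains


def _pack(chains: list[np.ndarray], values: np.ndarray):
    """Pad per-chain observation vectors into an (n_chains, L_max) matrix."""
    lengths = np.array([c.size for c in chains])
    lmax = int(lengths.max())
    x = np.zeros((len(chains), lmax))
    valid = np.zeros((len(chains), lmax), dtype=bool)
    for i, idx in enumerate(chains):
        x[i, : idx.size] = values[idx]
        valid[i, : idx.size] = True
    return x, valid, lengths


def _emission_loglik(x: np.ndarray, valid: np.ndarray, model: HMMModel) -> np.ndarray:
    """(C, L, K) Gaussian log-densities; exactly 0 at padded steps."""
    var = model.variance
    diff = x[:, :, None] - model.means[None, None, :]
    logb = -0.5 * diff * diff / var - 0.5 * math.log(2.0 * math.pi * var)
    logb[~valid] = 0.0
    return logb


def _fb_packed(model: HMMModel, logb: np.ndarray, valid: np.ndarray):
    """Scaled forward–backward over padded chains.

    Returns packed gamma (C, L, K), per-step scale terms and total loglik.
    """
    c_n, lmax, k = logb.shape
    a = model.transition
    m = logb.max(axis=2)
    m[~valid] = 0.0
    b = np.exp(logb - m[:, :, None])
    b[~valid] = 1.0

    alpha = np.empty((c_n, lmax, k))
    scale = np.empty((c_n, lmax))
    af = model.initial[None, :] * b[:, 0, :]
    s = af.sum(axis=1)
    alpha[:, 0] = af / s[:, None]
    scale[:, 0] = s
    for t in range(1, lmax):
        af = (alpha[:, t - 1] @ a) * b[:, t]
        s = af.sum(axis=1)
        alpha[:, t] = af / s[:, None]
        scale[:, t] = s

    gamma = np.empty((c_n, lmax, k))
    beta = np.ones((c_n, k))
    gamma[:, lmax - 1] = alpha[:, lmax - 1]
    for t in range(lmax - 2, -1, -1):
        beta = ((b[:, t + 1] * beta) @ a.T) / scale[:, t + 1][:, None]
        gamma[:, t] = alpha[:, t] * beta
    gamma /= gamma.sum(axis=2, keepdims=True)

    loglik = float((np.log(scale) + m).sum())
    return gamma, loglik


def forward_backward(model: HMMModel, obs: RatioProfile) -> PosteriorMatrix:
    """State posteriors per target and the total observation log-likelihood."""
    chains = _chains(obs)
    x, valid, _ = _pack(chains, obs.values)
    logb = _emission_loglik(x, valid, model)
    gamma_packed, loglik = _fb_packed(model, logb, valid)
    if not np.isfinite(loglik):
        raise NumericalError("non-finite log-likelihood in forward-backward")
    gamma = np.full((len(obs.values), model.n_states), np.nan)
    for i, idx in enumerate(chains):
        gamma[idx] = gamma_packed[i, : idx.size]
    return PosteriorMatrix(gamma=gamma, loglik=loglik, copy_numbers=model.copy_numbers)


def _preference_rank(copy_numbers: tuple[int, ...]) -> np.ndarray:
    """Tie-break rank: copy number closest to 2 wins, then the lower one."""
    order = sorted(range(len(copy_numbers)), key=lambda i: (abs(copy_numbers[i] - 2), copy_numbers[i]))
    rank = np.empty(len(copy_numbers), dtype=np.int64)
    for pos, state in enumerate(order):
        rank[state] = pos
    return rank


def viterbi(model: HMMModel, obs: RatioProfile) -> np.ndarray:
    """Most probable copy-number path, per chromosome chain.

    Returns an integer array aligned to the grid with the decoded copy number
    at unmasked targets and -1 at masked ones.  Exact likelihood ties break
    toward the copy number closest to 2, then toward the lower one.
    """
    chains = _chains(obs)
    x, valid, lengths = _pack(chains, obs.values)
    logb = _emission_loglik(x, valid, model)
    c_n, lmax, k = logb.shape
    log_a = np.log(model.transition)
    rank = _preference_rank(model.copy_numbers)

    delta = np.empty((c_n, lmax, k))
    ptr = np.zeros((c_n, lmax, k), dtype=np.int64)
    with np.errstate(divide="ignore"):
        log_init = np.log(model.initial)
    delta[:, 0] = log_init[None, :] + logb[:, 0]
    for t in range(1, lmax):
        scores = delta[:, t - 1][:, :, None] + log_a[None, :, :]  # (C, from, to)
        best = scores.max(axis=1)
        tied = scores == best[:, None, :]
        ptr[:, t] = np.where(tied, rank[None, :, None], k + 1).argmin(axis=1)
        delta[:, t] = best + logb[:, t]

    path = np.full(len(obs.values), -1, dtype=np.int64)
    cn_arr = np.asarray(model.copy_numbers)
    for i, idx in enumerate(chains):
        t_end = int(lengths[i]) - 1
        d = delta[i, t_end]
        tied = d == d.max()
        state = int(np.where(tied, rank, k + 1).argmin())
        states = np.empty(t_end + 1, dtype=np.int64)
        states[t_end] = state
        for t in range(t_end, 0, -1):
            state = int(ptr[i, t, state])
            states[t - 1] = state
        path[idx] = cn_arr[states]
    return path


def em_fit(
    model: HMMModel,
    obs: RatioProfile,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> HMMModel:
    """EM re-estimation of the shared variance and a global mean offset.

    The offset shifts all state means together (fixed copy-number spacing);
    transitions and the initial distribution are not re-estimated.  Stops
    when the relative log-likelihood improvement drops below *tol* or after
    *max_iter* iterations.  The returned model records the per-iteration
    log-likelihoods in ``em_history``.
    """
    if obs.n_unmasked < 50:
        raise ValidationError(
            f"EM needs at least 50 unmasked targets, got {obs.n_unmasked}"
        )
    chains = _chains(obs)
    x, valid, _ = _pack(chains, obs.values)
    base = model.means.copy()
    xs = x[valid]

    def loglik_at(offset: float, var: float) -> tuple[np.ndarray, float]:
        cur = replace(model, means=base + offset, variance=var)
        logb = _emission_loglik(x, valid, cur)
        return _fb_packed(cur, logb, valid)

    # The (offset, state-assignment) decomposition is multimodal: an offset
    # near half the state spacing can equally be read as a baseline shift or
    # as a genome-wide state change, and plain EM from 0 may land in the
    # wrong basin.  Score the candidate offsets that align the data mean
    # with each state and start EM from the best-scoring one (ties prefer
    # the smaller baseline shift).
    xbar = float(xs.mean())
    candidates = [0.0] + [xbar - float(b) for b in base]
    scored = []
    for off0 in candidates:
        _, ll0 = loglik_at(off0, float(model.variance))
        scored.append((off0, ll0))
    offset = min(scored, key=lambda s: (-s[1], abs(s[0])))[0]

    var = float(model.variance)
    history: list[float] = []
    prev_ll: float | None = None
    for it in range(max_iter):
        gamma_packed, ll = loglik_at(offset, var)
        if not np.isfinite(ll):
            raise NumericalError(f"non-finite log-likelihood at EM iteration {it}")
        history.append(ll)
        if prev_ll is not None and ll - prev_ll < tol * abs(prev_ll):
            break
        g = gamma_packed[valid]  # (n_unmasked, K)
        offset = float((xs - g @ base).mean())
        diff = xs[:, None] - base[None, :] - offset
        var = max(float((g * diff * diff).sum() / len(xs)), VARIANCE_FLOOR)
        prev_ll = ll

    fitted = replace(model, means=base + offset, variance=var)
    fitted.em_history = history
    return fitted


def decode_to_segments(
    path: np.ndarray,
    grid: TargetGrid,
    obs: RatioProfile,
    min_targets: int = 3,
) -> list[CNVCall]:
    """Turn a decoded copy-number path into unscored calls.

    Maximal runs of one non-diploid copy number over consecutive unmasked
    targets of one chromosome become calls; runs with fewer than
    *min_targets* member targets are discarded.
    """
    if min_targets < 1:
        raise ParameterError("min_targets must be >= 1")
    calls: list[CNVCall] = []
    for idx in _chains(obs):
        run_start = 0
        states = path[idx]
        for j in range(1, idx.size + 1):
            if j == idx.size or states[j] != states[run_start]:
                cn = int(states[run_start])
                run_len = j - run_start
                if cn != 2 and cn >= 0 and run_len >= min_targets:
                    first = int(idx[run_start])
                    last = int(idx[j - 1])
                    calls.append(
                        CNVCall(
                            sample_id=obs.sample_id,
                            chrom=grid.regions[first].chrom,
                            start=int(grid.starts[first]),
                            end=int(grid.ends[last]),
                            copy_number=cn,
                            first_target=first,
                            last_target=last,
                            n_targets=run_len,
                        )
                    )
                run_start = j
    return calls


def score_call(call: CNVCall, posterior: PosteriorMatrix) -> CNVCall:
    """Reliability score: 100 × mean posterior of the call's state, 1 decimal."""
    if call.first_target is None or call.last_target is None:
        raise ValidationError("call lacks grid ordinals; cannot score")
    k = posterior.copy_numbers.index(call.copy_number)
    rows = posterior.gamma[call.first_target : call.last_target + 1, k]
    rows = rows[np.isfinite(rows)]
    if rows.size == 0:
        raise ValidationError("posterior does not cover the call's targets")
    return replace(call, score=round(100.0 * float(rows.mean()), 1))


def filter_calls(calls: list[CNVCall], threshold: float = 80.0) -> list[CNVCall]:
    """Keep calls with score strictly greater than *threshold* (0–100)."""
    if not 0.0 <= threshold <= 100.0:
        raise ParameterError(f"score threshold {threshold} outside [0, 100]")
    return [c for c in calls if c.score > threshold]


@dataclass
class CallerConfig:
    """Tunable parameters of the calling pipeline (file + CLI overridable)."""

    states: tuple[int, ...] = (0, 1, 2, 3, 4)
    stay_prob: float = 0.99
    variance_init: float = 0.25
    min_targets: int = 3
    score_threshold: float = 80.0
    em_max_iter: int = 50
    em_tol: float = 1e-6
    gc_method: str = "median_bin"
    gc_bin_width: float = 0.02
    gc_min_bin: int = 10
    seed: int = 1

    @classmethod
    def from_mapping(cls, mapping: dict) -> "CallerConfig":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(mapping) - known
        if extra:
            raise ParameterError(f"unknown config keys: {sorted(extra)}")
        cfg = dict(mapping)
        if "states" in cfg:
            cfg["states"] = tuple(int(c) for c in cfg["states"])
        return cls(**cfg)

    @classmethod
    def from_yaml(cls, path: str) -> "CallerConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ParameterError(f"{path}: config must be a mapping")
        return cls.from_mapping(data)


def call_sample(
    patient: SampleCounts,
    reference: ReferenceProfile,
    grid: TargetGrid,
    config: CallerConfig | None = None,
) -> list[CNVCall]:
    """Full per-sample pipeline: observations -> EM -> Viterbi -> score -> filter.

    Deterministic given inputs and config.
    """
    config = config or CallerConfig()
    obs = make_observations(
        patient,
        grid,
        reference=reference,
        gc_method=config.gc_method,
        bin_width=config.gc_bin_width,
        min_bin=config.gc_min_bin,
    )
    model = init_model(
        expected_variance=config.variance_init,
        copy_numbers=config.states,
        stay_prob=config.stay_prob,
    )
    if obs.n_unmasked >= 50:
        model = em_fit(model, obs, max_iter=config.em_max_iter, tol=config.em_tol)
    path = viterbi(model, obs)
    segments = decode_to_segments(path, grid, obs, min_targets=config.min_targets)
    posterior = forward_backward(model, obs)
    scored = [score_call(c, posterior) for c in segments]
    return filter_calls(scored, threshold=config.score_threshold)
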