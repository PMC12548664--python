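"""Shapley-value attribution of classification accuracy to subnetworks.

Players are the subnetworks of a parcellation.  The characteristic function
v(S) is the test accuracy of a trained model when every ROI outside the
coalition S is masked out of the (Z-normalized) input tensor by zeroing its
rows and columns — zero being the per-edge mean after normalization, i.e. the
least informative value.  The Shapley value

    phi_i(v) = sum_{S subseteq N\\{i}} |S|! (|N|-|S|-1)! / |N|! * (v(S u {i}) - v(S))

is each subnetwork's average marginal contribution to accuracy over all
orders in which subnetworks could be added.  For small player sets (the
7-network case: 2^7 = 128 coalitions) the exact sum is evaluated with a
coalition cache; for larger sets (17 networks, or per-ROI players) a
permutation-sampling Monte-Carlo estimator is used, sharing the same cache.

v(S) evaluates the model *trained on full, unmasked data* against masked test
inputs; retraining for every coalition would multiply training cost by 2^|N|
per repetition.  A retrain-per-coalition mode is available for sensitivity
analysis.  v(empty set) is the measured accuracy on the all-zero tensor (a
constant prediction), not an assumed chance level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import ParcellationMap, TemporalNetwork
from .clf import RepetitionRecord, TrainConfig, accuracy, train_once
from .netbuild import apply_normalizer

__all__ = [
    "CoalitionGame",
    "ShapleyReport",
    "mask_coalition",
    "exact_shapley",
    "sampled_shapley",
    "make_accuracy_game",
    "attribute",
]

EXACT_PLAYER_GUARD = 20


class CoalitionGame:
    """A cooperative game: ordered players plus a cached characteristic
    function.  Coalitions are cached by bitmask, so repeated evaluations —
    across the exact sum or across sampled permutations — cost one call."""

    def __init__(self, players, value_fn):
        self.players = list(players)
        if len(set(self.players)) != len(self.players):
            raise ValueError("duplicate players")
        self._index = {p: i for i, p in enumerate(self.players)}
        self._value_fn = value_fn
        self.cache: dict[int, float] = {}

    @property
    def n_players(self) -> int:
        return len(self.players)

    def _mask_of(self, coalition) -> int:
        mask = 0
        for p in coalition:
            if p not in self._index:
                raise KeyError(
                    f"unknown player {p!r}; known players: {self.players}")
            mask |= 1 << self._index[p]
        return mask

    def value(self, coalition) -> float:
        """v(S), memoized on the coalition bitmask."""
        mask = coalition if isinstance(coalition, int) else self._mask_of(coalition)
        if mask not in self.cache:
            members = [p for i, p in enumerate(self.players) if mask >> i & 1]
            self.cache[mask] = float(self._value_fn(members))
        return self.cache[mask]

    @property
    def n_evaluations(self) -> int:
        return len(self.cache)


def mask_coalition(X: np.ndarray, keep, parcellation: ParcellationMap) -> np.ndarray:
    """Zero rows and columns of every time slice for ROIs outside ``keep``.

    Entries among kept ROIs are untouched.  Intended for Z-normalized
    tensors, where 0 is the per-edge mean.
    """
    known = set(parcellation.subnetworks)
    keep = set(keep)
    unknown = keep - known
    if unknown:
        raise KeyError(
            f"unknown subnetwork label(s) {sorted(unknown)}; known labels: "
            f"{sorted(known)}")
    drop = np.isin(parcellation.labels, list(known - keep))
    out = X.copy()
    out[drop, :, :] = 0.0
    out[:, drop, :] = 0.0
    return out


def exact_shapley(game: CoalitionGame) -> dict:
    """Exact Shapley values by enumerating all 2^|N| coalitions (cached).

    Satisfies efficiency, symmetry, dummy and additivity by construction of
    the weighted-marginal sum.
    """
    n = game.n_players
    if n > EXACT_PLAYER_GUARD:
        raise ValueError(
            f"|N|={n} exceeds the exact-enumeration guard "
            f"({EXACT_PLAYER_GUARD}); use sampled_shapley")
    fact = [math.factorial(k) for k in range(n + 1)]
    denom = fact[n]
    phi = np.zeros(n)
    for mask in range(1 << n):
        size = mask.bit_count()
        if size == n:
            continue
        v_s = game.value(mask)
        for i in range(n):
            if mask >> i & 1:
                continue
            w = fact[size] * fact[n - size - 1] / denom
            phi[i] += w * (game.value(mask | (1 << i)) - v_s)
    return {p: float(phi[i]) for i, p in enumerate(game.players)}


@dataclass
class SampledShapley:
    """Permutation-sampling estimate with its per-player sampling spread."""

    phi: dict
    marginals: np.ndarray  # (n_samples, n_players)
    n_samples: int

    def standard_error(self) -> dict:
        se = self.marginals.std(axis=0, ddof=1) / np.sqrt(self.n_samples)
        return {p: float(se[i]) for i, p in enumerate(self.phi)}


def sampled_shapley(game: CoalitionGame, n_samples: int = 100,
                    seed: int = 0) -> SampledShapley:
    """Monte-Carlo Shapley estimate from uniform random player orderings.

    Each sampled ordering contributes one marginal v(pred u {i}) - v(pred)
    per player, so the estimator is unbiased for the exact value and has
    zero variance on additive games.  The coalition cache is shared across
    samples.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    n = game.n_players
    rng = np.random.default_rng(seed)
    marginals = np.zeros((n_samples, n))
    for s in range(n_samples):
        order = rng.permutation(n)
        mask = 0
        v_prev = game.value(mask)
        for i in order:
            mask |= 1 << int(i)
            v_new = game.value(mask)
            marginals[s, i] = v_new - v_prev
            v_prev = v_new
    phi = marginals.mean(axis=0)
    return SampledShapley(
        phi={p: float(phi[i]) for i, p in enumerate(game.players)},
        marginals=marginals, n_samples=n_samples)


def make_accuracy_game(model, test_tensors: list[np.ndarray],
                       test_y: np.ndarray,
                       parcellation: ParcellationMap,
                       players=None) -> CoalitionGame:
    """Game whose value is the model's accuracy on coalition-masked inputs."""
    players = list(players) if players is not None else parcellation.subnetworks

    def v(coalition):
        masked = [mask_coalition(X, coalition, parcellation)
                  for X in test_tensors]
        return accuracy(model, masked, test_y)

    return CoalitionGame(players, v)


@dataclass
class ShapleyReport:
    """Per-player mean +/- sd of phi across training repetitions."""

    players: list
    per_repetition: list[dict]
    method: str
    n_samples: int | None = None
    efficiency_gaps: list[float] = field(default_factory=list)

    def mean(self) -> dict:
        return {p: float(np.mean([rep[p] for rep in self.per_repetition]))
                for p in self.players}

    def sd(self) -> dict:
        return {p: float(np.std([rep[p] for rep in self.per_repetition]))
                for p in self.players}

    def top_player(self):
        means = self.mean()
        return max(means, key=means.get)

    def summary(self) -> dict:
        mean, sd = self.mean(), self.sd()
        return {str(p): {"mean": mean[p], "sd": sd[p]} for p in self.players}


def attribute(records: list[RepetitionRecord], networks: list[TemporalNetwork],
              y: np.ndarray, parcellation: ParcellationMap, *,
              method: str = "exact", n_samples: int = 100, seed: int = 0,
              players=None, retrain_per_coalition: bool = False,
              model_cfg=None, train_cfg: TrainConfig | None = None,
              ) -> ShapleyReport:
    """Shapley attribution per training repetition, aggregated across them.

    For each repetition the game is built from that repetition's trained
    model, its normalizer, and *its own* test split; phi is computed exactly
    or by permutation sampling, then mean +/- sd per player is reported
    across repetitions.  Efficiency gaps |sum phi - (v(N) - v(empty))| are
    recorded per repetition (identically ~0 for the exact method).
    """
    if method not in ("exact", "sampled"):
        raise ValueError(f"unknown method {method!r}")
    if not records:
        raise ValueError("no repetition records to attribute")
    y = np.asarray(y, dtype=int)
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                 for s in ss.spawn(len(records))]
    player_list = list(players) if players is not None else parcellation.subnetworks
    per_rep, gaps = [], []
    for rec, rep_seed in zip(records, rep_seeds):
        test_tensors = [
            apply_normalizer(networks[i], rec.normalizer).tensor
            for i in rec.test_idx]
        test_y = y[rec.test_idx]
        if retrain_per_coalition:
            if model_cfg is None or train_cfg is None:
                raise ValueError(
                    "retrain_per_coalition needs model_cfg and train_cfg")
            train_tensors = [
                apply_normalizer(networks[i], rec.normalizer).tensor
                for i in rec.train_idx]
            train_y = y[rec.train_idx]

            def v(coalition):
                m_tr = [mask_coalition(X, coalition, parcellation)
                        for X in train_tensors]
                m_te = [mask_coalition(X, coalition, parcellation)
                        for X in test_tensors]
                model = train_once(m_tr, train_y, model_cfg, train_cfg,
                                   seed=rec.seed)
                return accuracy(model, m_te, test_y)

            game = CoalitionGame(player_list, v)
        else:
            game = make_accuracy_game(rec.model, test_tensors, test_y,
                                      parcellation, players=player_list)
        if method == "exact":
            phi = exact_shapley(game)
        else:
            phi = sampled_shapley(game, n_samples=n_samples,
                                  seed=rep_seed).phi
        full = game.value(game.players)
        empty = game.value([])
        gaps.append(abs(sum(phi.values()) - (full - empty)))
        per_rep.append(phi)
    return ShapleyReport(players=player_list, per_repetition=per_rep,
                         method=method,
                         n_samples=n_samples if method == "sampled" else None,
                         efficiency_gaps=gaps)
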