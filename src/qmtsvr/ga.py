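"""Genetic-algorithm hyperparameter search for the quasi multitask SVR.

Hyperparameters (C, eps, the t(t+1)/2 bandwidths theta_kk', and the
t(t-1)/2 association constants rho_kk') are encoded as fixed-point binary
segments on one chromosome. Each GA generation evaluates a population of
PS candidate models by forward validation inside the training data,
selects parents by tournament, produces children by two-point crossover
and per-bit mutation, and carries the v best chromosomes of the previous
generation over the v worst children (elitism). With the default
NG = 30 and PS = 25 a run assesses 750 candidate models; duplicate
chromosomes are served from a fitness cache without changing that
accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import QMTSVR
from .simdata import GenotypeMatrix, PhenotypeTable, Split

__all__ = [
    "ParamSpec",
    "SearchSpace",
    "GAConfig",
    "GAResult",
    "decode",
    "encode_random",
    "tournament_select",
    "crossover_mutate",
    "evaluate_fitness",
    "run_ga",
    "tune_qmtsvr",
    "default_search_space",
]


@dataclass(frozen=True)
class ParamSpec:
    name: str
    lower: float
    upper: float
    n_bits: int = 8

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: lower bound must be below upper")
        if self.n_bits < 1:
            raise ValueError(f"{self.name}: need at least one bit")


@dataclass
class SearchSpace:
    """Tunable parameters plus any fixed a-priori values (e.g. rho)."""

    params: list[ParamSpec]
    fixed: dict = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return len(self.params)

    @property
    def n_bits(self) -> int:
        return sum(p.n_bits for p in self.params)

    def names(self) -> list[str]:
        return [p.name for p in self.params]


def default_search_space(
    n_traits: int = 2, rho_fixed=None, n_bits: int = 8
) -> SearchSpace:
    """The QMTSVR search space with the standard bounds.

    C in [0.1, 4], eps in [1e-4, 0.1], every bandwidth theta_kk' in
    [0.2, 7] and every rho_kk' in [0.1, 0.3]; for t traits the space is
    2 + t^2 dimensional, dropping to 2 + t(t+1)/2 when rho is fixed a
    priori (e.g. at a known genetic correlation).
    """
    t = n_traits
    params = [
        ParamSpec("C", 0.1, 4.0, n_bits),
        ParamSpec("eps", 1e-4, 0.1, n_bits),
    ]
    for k in range(t):
        for kp in range(k, t):
            params.append(ParamSpec(f"theta_{k + 1}{kp + 1}", 0.2, 7.0, n_bits))
    fixed = {}
    for k in range(t):
        for kp in range(k + 1, t):
            name = f"rho_{k + 1}{kp + 1}"
            if rho_fixed is None:
                params.append(ParamSpec(name, 0.1, 0.3, n_bits))
            else:
                fixed[name] = float(
                    rho_fixed if np.isscalar(rho_fixed) else rho_fixed[(k, kp)]
                )
    return SearchSpace(params=params, fixed=fixed)


def decode(bits: np.ndarray, space: SearchSpace) -> dict:
    """Fixed-point decode: lower + int(segment)/(2^n_bits - 1) * range."""
    bits = np.asarray(bits)
    if bits.shape != (space.n_bits,):
        raise ValueError(f"expected {space.n_bits} bits, got {bits.shape}")
    out = dict(space.fixed)
    pos = 0
    for p in space.params:
        seg = bits[pos : pos + p.n_bits]
        intval = int("".join("1" if b else "0" for b in seg), 2)
        out[p.name] = p.lower + intval / (2**p.n_bits - 1) * (p.upper - p.lower)
        pos += p.n_bits
    return out


def encode_random(space: SearchSpace, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 2, size=space.n_bits, dtype=np.uint8)


def tournament_select(
    fitness: np.ndarray, tsize: int, rng: np.random.Generator
) -> int:
    """Index of the fittest among ``tsize`` uniform draws with replacement.

    Ties break at the lowest population index among the drawn candidates.
    """
    draws = rng.integers(0, len(fitness), size=tsize)
    draws = np.sort(draws)
    return int(draws[np.argmax(fitness[draws])])


def crossover_mutate(
    p1: np.ndarray,
    p2: np.ndarray,
    cr: float,
    mr: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Two-point crossover with probability ``cr``, then per-bit mutation.

    Without crossover the child is a copy of one parent chosen uniformly;
    with it, the segment between two uniform cut points of parent 1 is
    replaced by parent 2's.
    """
    if len(p1) != len(p2):
        raise ValueError("parents must have equal length")
    L = len(p1)
    if rng.random() < cr:
        cuts = np.sort(rng.integers(0, L + 1, size=2))
        child = p1.copy()
        child[cuts[0] : cuts[1]] = p2[cuts[0] : cuts[1]]
    else:
        child = (p1 if rng.random() < 0.5 else p2).copy()
    flips = rng.random(L) < mr
    child = child.copy()
    child[flips] ^= 1
    return child


@dataclass
class GAConfig:
    """GA control parameters (defaults: NG=30, PS=25, CR=0.9, MR=0.05,
    tsize=4, one elite)."""

    ng: int = 30
    ps: int = 25
    cr: float = 0.9
    mr: float = 0.05
    tsize: int = 4
    elitism: int = 1
    seed: int = 0

    def __post_init__(self):
        if not self.ps >= self.tsize >= 2:
            raise ValueError("require PS >= tsize >= 2")
        if not (0.0 <= self.cr <= 1.0 and 0.0 <= self.mr <= 1.0):
            raise ValueError("CR and MR must lie in [0, 1]")
        if not 0 <= self.elitism < self.ps:
            raise ValueError("elitism count must lie in [0, PS)")


@dataclass
class GAResult:
    best_params: dict
    best_fitness: float
    best_bits: np.ndarray
    history: pd.DataFrame
    n_candidates: int
    n_unique_fits: int

    def plot_history(self, ax=None):
        """Best and mean fitness per GA generation."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history["generation"], self.history["best_fs"], label="best")
        ax.plot(self.history["generation"], self.history["mean_fs"], label="mean")
        ax.set_xlabel("GA generation")
        ax.set_ylabel("fitness (validation correlation)")
        ax.legend()
        return ax


def _bits_int(bits: np.ndarray) -> int:
    return int("".join("1" if b else "0" for b in bits), 2)


def run_ga(space: SearchSpace, config: GAConfig, fitness_fn) -> GAResult:
    """Run the GA; ``fitness_fn(params_dict) -> float`` is maximized.

    Deterministic given ``config.seed``: identical seed and configuration
    replay the identical history. The best-ever candidate is tracked with
    ties broken toward smaller C, then smaller chromosome integer value.
    """
    rng = np.random.default_rng(config.seed)
    cache: dict[bytes, float] = {}
    n_candidates = 0

    def fitness_of(bits: np.ndarray) -> float:
        nonlocal n_candidates
        n_candidates += 1
        key = bits.tobytes()
        if key not in cache:
            fs = fitness_fn(decode(bits, space))
            cache[key] = float(fs) if np.isfinite(fs) else -1.0
        return cache[key]

    pop = [encode_random(space, rng) for _ in range(config.ps)]
    fs = np.array([fitness_of(b) for b in pop])

    best_bits, best_fs = None, -np.inf
    records = []

    def consider(bits, f):
        nonlocal best_bits, best_fs
        if f > best_fs:
            best_bits, best_fs = bits.copy(), f
        elif f == best_fs and best_bits is not None:
            cand, inc = decode(bits, space), decode(best_bits, space)
            if (cand.get("C", 0.0), _bits_int(bits)) < (
                inc.get("C", 0.0),
                _bits_int(best_bits),
            ):
                best_bits = bits.copy()

    def log(gen):
        for b, f in zip(pop, fs):
            consider(b, f)
        bp = decode(best_bits, space)
        rec = {
            "generation": gen,
            "best_fs": best_fs,
            "mean_fs": float(fs.mean()),
            "candidates_evaluated": n_candidates,
        }
        rec.update({f"best_{k}": v for k, v in bp.items()})
        records.append(rec)

    log(0)
    for gen in range(1, config.ng):
        children = []
        for _ in range(config.ps):
            i = tournament_select(fs, config.tsize, rng)
            j = tournament_select(fs, config.tsize, rng)
            children.append(crossover_mutate(pop[i], pop[j], config.cr, config.mr, rng))
        child_fs = np.array([fitness_of(b) for b in children])
        if config.elitism > 0:
            v = config.elitism
            worst = np.argsort(child_fs)[:v]
            best_prev = np.argsort(fs)[::-1][:v]
            for w, b in zip(worst, best_prev):
                children[w] = pop[b].copy()
                child_fs[w] = fs[b]
        pop, fs = children, child_fs
        log(gen)

    return GAResult(
        best_params=decode(best_bits, space),
        best_fitness=float(best_fs),
        best_bits=best_bits,
        history=pd.DataFrame.from_records(records),
        n_candidates=n_candidates,
        n_unique_fits=len(cache),
    )


def _params_to_theta_rho(params: dict, t: int):
    iu = np.triu_indices(t)
    theta = np.zeros((t, t))
    for k, kp in zip(*iu):
        theta[k, kp] = theta[kp, k] = params[f"theta_{k + 1}{kp + 1}"]
    rho = np.eye(t)
    for k in range(t):
        for kp in range(k + 1, t):
            rho[k, kp] = rho[kp, k] = params.get(f"rho_{k + 1}{kp + 1}", 0.0)
    return theta, rho


def evaluate_fitness(
    params: dict,
    model: QMTSVR,
    inner_split: Split,
) -> float:
    """Validation-correlation fitness of one hyperparameter combination.

    Fits the model's design on the inner-training generations and
    returns the Pearson correlation between predicted and observed
    target-trait values in the inner-validation generations. Any failure
    (solver breakdown, constant predictions, missing variance) maps to
    the worst fitness, -1.
    """
    inner_model = QMTSVR(
        model.pheno,
        model.geno,
        inner_split,
        target_trait=model.target,
        design=model.design,
        traits=model.traits,
        weighted=model.weighted,
        kernel_kind=model.kernel_kind,
    )
    inner_model.set_sq_edm(model.sq_edm())
    if model.weighted:
        inner_model.set_pair_weights(model.pair_weights())
    t = model.n_traits
    theta, rho = _params_to_theta_rho(params, t)
    try:
        res = inner_model.fit(C=params["C"], eps=params["eps"], theta=theta, rho=rho)
    except Exception:
        return -1.0
    y_obs = model.pheno.trait_values[inner_split.test_idx, model.target]
    y_pred = res.predicted_values
    ok = np.isfinite(y_obs)
    if ok.sum() < 3 or np.std(y_pred[ok]) == 0 or np.std(y_obs[ok]) == 0:
        return -1.0
    r = float(np.corrcoef(y_obs[ok], y_pred[ok])[0, 1])
    return r if np.isfinite(r) else -1.0


def tune_qmtsvr(
    pheno: PhenotypeTable,
    geno: GenotypeMatrix,
    split: Split,
    inner_validation_generations,
    target_trait: int | str = 0,
    design: str = "CV2",
    weighted: bool = False,
    space: SearchSpace | None = None,
    config: GAConfig | None = None,
) -> GAResult:
    """GA-tune a QMTSVR and return the best hyperparameter set.

    The fitness of each candidate is its forward-validation correlation
    on ``inner_validation_generations`` (withheld from the inner training
    data); after tuning, refit on the full training split with
    ``GAResult.best_params``.
    """
    model = QMTSVR(
        pheno, geno, split, target_trait=target_trait, design=design, weighted=weighted
    )
    inner_split = split.inner(pheno, inner_validation_generations)
    if space is None:
        space = default_search_space(model.n_traits)
    if config is None:
        config = GAConfig()
    model.sq_edm()  # build once, shared across all candidate evaluations
    if weighted:
        model.pair_weights()
    return run_ga(space, config, lambda p: evaluate_fitness(p, model, inner_split))
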