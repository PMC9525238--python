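"""Bayesian estimation of habitat transition rates over tree sets.

The sampler targets the posterior of the 2-state rate matrix (or of
clade-specific matrices on a painted tree) under the hierarchical prior
used throughout the package: a rate-mean hyperparameter m ~ Uniform(0, 2)
and rates q_i | m ~ Exponential(mean m), with a reversible-jump move
between the equal-rates model (one free rate, q_MN = q_NM) and the
unequal-rates model (two free rates), each with prior probability 1/2.
Phylogenetic uncertainty enters through a tree index over the supplied
tree set, refreshed by Metropolis-accepted uniform proposals (or by the
fixed-schedule "cycle" mode that spends a block of generations on each
tree in turn).

Marginal likelihoods are estimated by stepping-stone sampling along a
ladder of power posteriors, and models are compared on the scale
log BF = 2 x (log Z_A - log Z_B), with >= 10 read as decisive.

:func:`run_clade_analysis` orchestrates the per-clade workflow: tip-count
and habitat eligibility, posterior rate summaries (directional rates and
the normalized global rate), equal- vs unequal-rates model comparison, and
the sampling-effort sensitivity grid.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .ctmc import RateModel, RootPolicy, TreeLikelihood, normalize
from .phylo_io import (
    AnnotatedTree,
    Habitat,
    TreeSet,
    read_tree_set,
    read_habitat_table,
    subsample_tips,
)

log = logging.getLogger(__name__)

__all__ = [
    "PriorSpec",
    "SteppingStoneConfig",
    "ModelSpace",
    "PosteriorSample",
    "SteppingStoneResult",
    "ModelComparison",
    "sample_posterior",
    "stepping_stone",
    "compare_models",
    "subsample_tree_set",
    "run_clade_analysis",
]

EQUAL, UNEQUAL = 0, 1


@dataclass(frozen=True)
class PriorSpec:
    """Hierarchical prior: m ~ U(bounds), q_i | m ~ Exp(mean m).

    ``fixed_mean`` pins the hyperparameter (no m moves), which turns the
    rate prior into a plain exponential — useful for oracle checks.
    ``p_equal`` is the prior probability of the equal-rates model.
    """

    hyper_mean_bounds: tuple[float, float] = (0.0, 2.0)
    fixed_mean: float | None = None
    p_equal: float = 0.5

    def __post_init__(self) -> None:
        lo, hi = self.hyper_mean_bounds
        if not (0.0 <= lo < hi):
            raise ValueError("invalid hyper-mean bounds")
        if self.fixed_mean is not None and self.fixed_mean <= 0:
            raise ValueError("fixed_mean must be positive")
        if not 0.0 < self.p_equal < 1.0:
            raise ValueError("p_equal must be in (0, 1)")

    def log_rate_density(self, q: float, m: float) -> float:
        if q < 0:
            return -math.inf
        return -math.log(m) - q / m


@dataclass(frozen=True)
class SteppingStoneConfig:
    """Power-posterior ladder: K stones, beta_k = (k/K)^(1/alpha)."""

    n_stones: int = 50
    chain_length: int = 5000
    alpha: float = 0.4
    burn_in_frac: float = 0.5

    def betas(self) -> np.ndarray:
        k = np.arange(self.n_stones + 1)
        return (k / self.n_stones) ** (1.0 / self.alpha)


@dataclass
class ModelSpace:
    """What the chain samples over.

    ``clade_defs=None`` is the homogeneous model (one rate regime for the
    whole tree); a clade map gives each named, monophyletic clade its own
    regime (stem branch included) with the remainder in ``background``.
    ``rates`` restricts the within-regime model: "rj" (default) jumps
    between equal and unequal rates; "equal"/"unequal" pin it.
    """

    clade_defs: dict[str, set] | None = None
    rates: str = "rj"
    background: str = "background"

    def __post_init__(self) -> None:
        if self.rates not in ("rj", "equal", "unequal"):
            raise ValueError("rates must be 'rj', 'equal' or 'unequal'")

    @property
    def regime_names(self) -> list[str]:
        if self.clade_defs is None:
            return [self.background]
        return [self.background] + sorted(self.clade_defs)


@dataclass
class PosteriorSample:
    """Post-burn-in MCMC draws plus chain metadata."""

    draws: pd.DataFrame
    regime_names: list[str]
    meta: dict = field(default_factory=dict)

    def rates(self, regime: str | None = None) -> pd.DataFrame:
        name = regime or self.regime_names[0]
        return self.draws[[f"q_mn[{name}]", f"q_nm[{name}]"]].rename(
            columns={f"q_mn[{name}]": "q_mn", f"q_nm[{name}]": "q_nm"}
        )

    def p_equal(self, regime: str | None = None) -> float:
        name = regime or self.regime_names[0]
        return float((self.draws[f"k[{name}]"] == EQUAL).mean())

    def summary(self, regime: str | None = None) -> dict:
        r = self.rates(regime)
        glob = np.array(
            [
                normalize(RateModel(a, b))[1] if a + b > 0 else 0.0
                for a, b in zip(r["q_mn"], r["q_nm"])
            ]
        )
        ratio = r["q_mn"] / np.maximum(r["q_nm"], 1e-300)
        return {
            "q_mn_mean": float(r["q_mn"].mean()),
            "q_mn_sd": float(r["q_mn"].std()),
            "q_nm_mean": float(r["q_nm"].mean()),
            "q_nm_sd": float(r["q_nm"].std()),
            "global_rate_mean": float(glob.mean()),
            "global_rate_sd": float(glob.std()),
            "rate_ratio_ci95": [
                float(np.quantile(ratio, 0.025)),
                float(np.quantile(ratio, 0.975)),
            ],
            "p_equal_rates": self.p_equal(regime),
            "n_draws": int(len(r)),
        }


@dataclass
class SteppingStoneResult:
    log_z: float
    se: float
    stones: pd.DataFrame
    meta: dict = field(default_factory=dict)


@dataclass
class ModelComparison:
    """2 x (log Z_A - log Z_B); >= threshold favours model A."""

    log_z_a: float
    log_z_b: float
    threshold: float = 10.0
    label_a: str = "heterogeneous"
    label_b: str = "homogeneous"

    @property
    def log_bayes_factor(self) -> float:
        return 2.0 * (self.log_z_a - self.log_z_b)

    @property
    def verdict(self) -> str:
        if self.log_bayes_factor >= self.threshold:
            return f"favour {self.label_a}"
        if self.log_bayes_factor <= -self.threshold:
            return f"favour {self.label_b}"
        return "no decisive preference"


def compare_models(
    log_z_het: float | SteppingStoneResult,
    log_z_hom: float | SteppingStoneResult,
    threshold: float = 10.0,
    label_a: str = "heterogeneous",
    label_b: str = "homogeneous",
) -> ModelComparison:
    a = log_z_het.log_z if isinstance(log_z_het, SteppingStoneResult) else log_z_het
    b = log_z_hom.log_z if isinstance(log_z_hom, SteppingStoneResult) else log_z_hom
    if not (math.isfinite(a) and math.isfinite(b)):
        raise ValueError("marginal likelihoods must be finite")
    return ModelComparison(a, b, threshold, label_a, label_b)


class _Chain:
    """Metropolis-within-reversible-jump chain over rates, m and tree index.

    ``power`` tempers the likelihood (beta in the power posterior); the
    prior is never tempered.  Proposal scales are auto-tuned toward a
    20-40% acceptance rate during burn-in and frozen afterwards.
    """

    RJ_SIGMA = 0.5

    def __init__(
        self,
        engines: Sequence[TreeLikelihood],
        space: ModelSpace,
        prior: PriorSpec,
        rng: np.random.Generator,
        power: float = 1.0,
        tree_mode: str = "mixed",
        tree_swap_every: int = 10,
        gens_per_tree: int | None = None,
    ):
        self.engines = list(engines)
        self.space = space
        self.prior = prior
        self.rng = rng
        self.power = power
        self.tree_mode = tree_mode
        self.tree_swap_every = max(1, tree_swap_every)
        self.gens_per_tree = gens_per_tree
        self.regimes = space.regime_names
        self.n_regimes = len(self.regimes)
        # state
        self.m = (
            prior.fixed_mean
            if prior.fixed_mean is not None
            else float(rng.uniform(*prior.hyper_mean_bounds))
        )
        start_k = EQUAL if space.rates in ("rj", "equal") else UNEQUAL
        self.k = [start_k] * self.n_regimes
        self.q = [
            [float(rng.exponential(self.m)), 0.0] for _ in range(self.n_regimes)
        ]
        for qr, kr in zip(self.q, self.k):
            qr[1] = qr[0] if kr == EQUAL else float(rng.exponential(self.m))
        self.tree_index = 0
        self.loglik = self._eval(self.tree_index)
        # proposal scales
        self.w_m = 0.3
        self.w_q = [0.8] * self.n_regimes
        self._acc = {"m": [0, 0], "q": [0, 0], "tree": [0, 0], "rj": [0, 0]}
        self.tuning = True
        self.n_evals = 1

    # -- likelihood ---------------------------------------------------------
    def _models(self) -> list[RateModel]:
        return [RateModel(qr[0], qr[1]) for qr in self.q]

    def _eval(self, tree_index: int) -> float:
        return self.engines[tree_index].loglik(self._models())

    def _mh(self, log_alpha: float) -> bool:
        return log_alpha >= 0 or math.log(self.rng.random()) < log_alpha

    # -- moves --------------------------------------------------------------
    def _free_rates(self) -> list[float]:
        out = []
        for kr, qr in zip(self.k, self.q):
            out.append(qr[0])
            if kr == UNEQUAL:
                out.append(qr[1])
        return out

    def move_m(self) -> None:
        if self.prior.fixed_mean is not None:
            return
        lo, hi = self.prior.hyper_mean_bounds
        m_new = self.m + float(self.rng.uniform(-self.w_m, self.w_m))
        self._acc["m"][1] += 1
        if not (lo < m_new <= hi):
            return
        delta = sum(
            self.prior.log_rate_density(q, m_new)
            - self.prior.log_rate_density(q, self.m)
            for q in self._free_rates()
        )
        if self._mh(delta):
            self.m = m_new
            self._acc["m"][0] += 1

    def move_rates(self) -> None:
        for r in range(self.n_regimes):
            n_free = 1 if self.k[r] == EQUAL else 2
            for slot in range(n_free):
                old = self.q[r][slot]
                if old <= 0:
                    old = 1e-12
                delta = float(self.rng.uniform(-self.w_q[r], self.w_q[r]))
                new = old * math.exp(delta)
                backup = (self.q[r][0], self.q[r][1])
                if self.k[r] == EQUAL:
                    self.q[r][0] = self.q[r][1] = new
                else:
                    self.q[r][slot] = new
                try:
                    ll_new = self._eval(self.tree_index)
                    self.n_evals += 1
                except ArithmeticError:
                    self.q[r][0], self.q[r][1] = backup
                    continue
                log_alpha = (
                    self.power * (ll_new - self.loglik)
                    + self.prior.log_rate_density(new, self.m)
                    - self.prior.log_rate_density(old, self.m)
                    + delta  # Jacobian of the log-scale slide
                )
                self._acc["q"][1] += 1
                if self._mh(log_alpha):
                    self.loglik = ll_new
                    self._acc["q"][0] += 1
                else:
                    self.q[r][0], self.q[r][1] = backup

    def move_rj(self) -> None:
        """Split/merge between equal- and unequal-rates within one regime.

        Merge sets both rates to their geometric mean; split perturbs by
        e^{+-u}, u ~ N(0, sigma).  The Jacobian of (q, u) -> (q e^u,
        q e^{-u}) is 2q.  Model prior is p_equal vs 1 - p_equal.
        """
        if self.space.rates != "rj":
            return
        r = int(self.rng.integers(self.n_regimes))
        sigma = self.RJ_SIGMA
        prior, m = self.prior, self.m
        log_model_ratio = math.log(1.0 - prior.p_equal) - math.log(prior.p_equal)
        backup = (self.k[r], self.q[r][0], self.q[r][1])
        self._acc["rj"][1] += 1
        if self.k[r] == EQUAL:
            q = self.q[r][0]
            if q <= 0:
                return
            u = float(self.rng.normal(0.0, sigma))
            q1, q2 = q * math.exp(u), q * math.exp(-u)
            self.k[r] = UNEQUAL
            self.q[r][0], self.q[r][1] = q1, q2
            log_phi = -0.5 * (u / sigma) ** 2 - math.log(sigma * math.sqrt(2 * math.pi))
            log_alpha_extra = (
                prior.log_rate_density(q1, m)
                + prior.log_rate_density(q2, m)
                - prior.log_rate_density(q, m)
                + log_model_ratio
                - log_phi
                + math.log(2.0 * q)
            )
        else:
            q1, q2 = self.q[r][0], self.q[r][1]
            if q1 <= 0 or q2 <= 0:
                return
            q = math.sqrt(q1 * q2)
            u = 0.5 * math.log(q1 / q2)
            self.k[r] = EQUAL
            self.q[r][0] = self.q[r][1] = q
            log_phi = -0.5 * (u / sigma) ** 2 - math.log(sigma * math.sqrt(2 * math.pi))
            log_alpha_extra = (
                prior.log_rate_density(q, m)
                - prior.log_rate_density(q1, m)
                - prior.log_rate_density(q2, m)
                - log_model_ratio
                + log_phi
                - math.log(2.0 * q)
            )
        try:
            ll_new = self._eval(self.tree_index)
            self.n_evals += 1
        except ArithmeticError:
            self.k[r], self.q[r][0], self.q[r][1] = backup
            return
        if self._mh(self.power * (ll_new - self.loglik) + log_alpha_extra):
            self.loglik = ll_new
            self._acc["rj"][0] += 1
        else:
            self.k[r], self.q[r][0], self.q[r][1] = backup

    def move_tree(self, gen: int) -> None:
        n = len(self.engines)
        if n == 1:
            return
        if self.tree_mode == "cycle":
            block = self.gens_per_tree or 1
            target = (gen // block) % n
            if target != self.tree_index:
                self.tree_index = target
                self.loglik = self._eval(target)
                self.n_evals += 1
            return
        if gen % self.tree_swap_every != 0:
            return
        proposal = int(self.rng.integers(n - 1))
        if proposal >= self.tree_index:
            proposal += 1
        ll_new = self._eval(proposal)
        self.n_evals += 1
        self._acc["tree"][1] += 1
        if self._mh(self.power * (ll_new - self.loglik)):
            self.tree_index = proposal
            self.loglik = ll_new
            self._acc["tree"][0] += 1

    def _tune(self) -> None:
        for key, scale_attr in (("m", "w_m"),):
            acc, tot = self._acc[key]
            if tot >= 40:
                rate = acc / tot
                if rate > 0.4:
                    self.w_m = min(self.w_m * 1.4, 2.0)
                elif rate < 0.2:
                    self.w_m /= 1.4
                self._acc[key] = [0, 0]
        acc, tot = self._acc["q"]
        if tot >= 40:
            rate = acc / tot
            for r in range(self.n_regimes):
                if rate > 0.4:
                    self.w_q[r] = min(self.w_q[r] * 1.4, 5.0)
                elif rate < 0.2:
                    self.w_q[r] /= 1.4
            self._acc["q"] = [0, 0]

    def step(self, gen: int) -> None:
        self.move_tree(gen)
        self.move_m()
        self.move_rates()
        self.move_rj()
        if self.tuning and gen % 100 == 99:
            self._tune()

    def freeze(self) -> None:
        self.tuning = False

    def acceptance_report(self) -> dict:
        return {
            key: (acc / tot if tot else None)
            for key, (acc, tot) in self._acc.items()
        }

    def snapshot(self, gen: int) -> dict:
        row: dict = {
            "gen": gen,
            "tree": self.tree_index,
            "m": self.m,
            "loglik": self.loglik,
        }
        for name, kr, qr in zip(self.regimes, self.k, self.q):
            row[f"k[{name}]"] = kr
            row[f"q_mn[{name}]"] = qr[0]
            row[f"q_nm[{name}]"] = qr[1]
        return row


def _build_engines(
    trees: TreeSet, space: ModelSpace, root: RootPolicy
) -> list[TreeLikelihood]:
    return [
        TreeLikelihood(
            at,
            clade_defs=space.clade_defs,
            background=space.background,
            root=root,
        )
        for at in trees
    ]


def sample_posterior(
    trees: TreeSet,
    model_space: ModelSpace | None = None,
    prior: PriorSpec | None = None,
    gens_per_tree: int = 1000,
    burn_in: int | None = None,
    seed: int = 0,
    thin: int | None = None,
    root: RootPolicy = RootPolicy.equal(),
    tree_mode: str = "mixed",
    tree_swap_every: int = 10,
    power: float = 1.0,
) -> PosteriorSample:
    """Sample the posterior over rates, model indicators and trees.

    Runs ``gens_per_tree x len(trees)`` generations in total ("cycle"
    tree mode spends that block on each tree in turn, reproducing a fixed
    per-tree schedule; "mixed" proposes Metropolis tree swaps every
    ``tree_swap_every`` generations).  ``burn_in`` defaults to half the
    total; the trace is deterministic given ``seed``.  ``power=0`` samples
    the prior alone.
    """
    space = model_space or ModelSpace()
    prior = prior or PriorSpec()
    total = gens_per_tree * len(trees)
    if burn_in is None:
        burn_in = total // 2
    if not 0 <= burn_in < total:
        raise ValueError("burn_in must be in [0, total generations)")
    if thin is None:
        thin = max(1, (total - burn_in) // 2000)
    rng = np.random.default_rng(seed)
    engines = _build_engines(trees, space, root)
    chain = _Chain(
        engines,
        space,
        prior,
        rng,
        power=power,
        tree_mode=tree_mode,
        tree_swap_every=tree_swap_every,
        gens_per_tree=gens_per_tree,
    )
    rows = []
    for gen in range(total):
        if gen == burn_in:
            chain.freeze()
        chain.step(gen)
        if gen >= burn_in and (gen - burn_in) % thin == 0:
            rows.append(chain.snapshot(gen))
    acc = chain.acceptance_report()
    if acc["q"] is not None and acc["q"] == 0.0:
        log.warning("zero rate-move acceptance; proposal scales: %s", chain.w_q)
    return PosteriorSample(
        draws=pd.DataFrame(rows),
        regime_names=space.regime_names,
        meta={
            "generations": total,
            "burn_in": burn_in,
            "thin": thin,
            "seed": seed,
            "tree_mode": tree_mode,
            "acceptance": acc,
            "n_likelihood_evals": chain.n_evals,
            "proposal_scales": {"m": chain.w_m, "q": list(chain.w_q)},
        },
    )


def _log_mean_exp(x: np.ndarray) -> tuple[float, float]:
    """(log mean exp(x), delta-method s.e. of it)."""
    hi = float(np.max(x))
    y = np.exp(x - hi)
    mean = float(np.mean(y))
    lme = hi + math.log(mean)
    if len(y) > 1 and mean > 0:
        se = float(np.std(y, ddof=1) / (math.sqrt(len(y)) * mean))
    else:
        se = 0.0
    return lme, se


def stepping_stone(
    trees: TreeSet,
    model_space: ModelSpace | None = None,
    prior: PriorSpec | None = None,
    cfg: SteppingStoneConfig | None = None,
    seed: int = 0,
    root: RootPolicy = RootPolicy.equal(),
    tree_mode: str = "mixed",
) -> SteppingStoneResult:
    """Stepping-stone estimate of the log marginal likelihood.

    Runs one power-posterior chain segment per stone at beta_{k-1}, and
    accumulates log Z = sum_k log-mean-exp((beta_k - beta_{k-1}) * loglik)
    over the post-burn-in samples of each segment; the chain state carries
    over between stones (warm starts up the ladder).  The Monte-Carlo
    standard error is the per-stone delta-method estimate, combined in
    quadrature.
    """
    space = model_space or ModelSpace()
    prior = prior or PriorSpec()
    cfg = cfg or SteppingStoneConfig()
    betas = cfg.betas()
    rng = np.random.default_rng(seed)
    engines = _build_engines(trees, space, root)
    chain = _Chain(
        engines,
        space,
        prior,
        rng,
        power=0.0,
        tree_mode=tree_mode,
        gens_per_tree=max(1, cfg.chain_length // max(1, len(trees))),
    )
    burn = int(cfg.chain_length * cfg.burn_in_frac)
    log_z = 0.0
    var = 0.0
    rows = []
    gen = 0
    for k in range(1, cfg.n_stones + 1):
        beta_lo, beta_hi = float(betas[k - 1]), float(betas[k])
        chain.power = beta_lo
        samples = []
        for i in range(cfg.chain_length):
            chain.step(gen)
            gen += 1
            if i >= burn:
                samples.append(chain.loglik)
        chain.freeze()  # tune only during the first stone's burn-in
        contrib, se = _log_mean_exp((beta_hi - beta_lo) * np.asarray(samples))
        if not math.isfinite(contrib):
            raise ArithmeticError(f"non-finite contribution at stone {k}")
        log_z += contrib
        var += se**2
        rows.append(
            {
                "stone": k,
                "beta_lo": beta_lo,
                "beta_hi": beta_hi,
                "contribution": contrib,
                "se": se,
                "n_samples": len(samples),
            }
        )
    return SteppingStoneResult(
        log_z=log_z,
        se=math.sqrt(var),
        stones=pd.DataFrame(rows),
        meta={"seed": seed, "config": cfg.__dict__, "acceptance": chain.acceptance_report()},
    )


def subsample_tree_set(
    trees: TreeSet, habitat: Habitat | str, fraction: float, seed: int
) -> TreeSet:
    """Remove one seeded random tip subset from every member tree.

    The removal set is drawn once from the shared labelling so all members
    keep identical tip sets, then each tree is pruned.
    """
    first = subsample_tips(trees[0], habitat, fraction, seed)
    keep = set(first.labels)
    members = [first]
    for at in list(trees)[1:]:
        clone = at.tree.clone(depth=1)
        drop = sorted(set(at.labels) - keep)
        if drop:
            clone.prune_taxa_with_labels(drop)
            clone.suppress_unifurcations()
        members.append(
            AnnotatedTree(clone, {t: h for t, h in at.labels.items() if t in keep})
        )
    return TreeSet(members)


def run_clade_analysis(
    config: Mapping | str | Path,
    report_path: str | Path | None = None,
) -> dict:
    """Per-clade rate analysis over a bundle of tree sets.

    ``config`` is a mapping (or YAML file path) with::

        clades:
          - name: fungi_like
            trees: fungi_like.trees.nwk     # one Newick per line
            habitats: fungi_like.habitats.tsv
        mcmc: {gens_per_tree: 500, burn_in: null, seed: 1}
        eligibility: {min_tips: 50}
        model_test: {enabled: true, n_stones: 20, chain_length: 1000,
                     threshold: 10}
        subsample: {fractions: [0.1, 0.3], habitats: [marine],
                    replicates: 2, gens_per_tree: 200}

    Ineligible clades (too few tips, or a single habitat) are skipped with
    the reason recorded, not fatal.  The per-clade model test compares
    unequal- against equal-rates marginal likelihoods by stepping stone;
    log BF >= threshold flags rate asymmetry (heterogeneity of direction).
    Returns (and optionally writes) a JSON-serializable report.
    """
    if isinstance(config, (str, Path)):
        base = Path(config).parent
        with open(config) as fh:
            config = yaml.safe_load(fh)
    else:
        base = Path(".")
    mcmc = dict(config.get("mcmc", {}))
    gens = int(mcmc.get("gens_per_tree", 500))
    burn = mcmc.get("burn_in")
    seed = int(mcmc.get("seed", 0))
    min_tips = int(config.get("eligibility", {}).get("min_tips", 50))
    mt_cfg = dict(config.get("model_test", {}) or {})
    ss_cfg = dict(config.get("subsample", {}) or {})
    report: dict = {
        "settings": {
            "gens_per_tree": gens,
            "burn_in": burn,
            "seed": seed,
            "min_tips": min_tips,
        },
        "clades": {},
    }
    for i, spec in enumerate(config["clades"]):
        name = spec["name"]
        entry: dict = {}
        report["clades"][name] = entry
        if isinstance(spec.get("trees"), TreeSet):
            trees = spec["trees"]
        else:
            table = read_habitat_table(str(base / spec["habitats"]))
            trees = read_tree_set(str(base / spec["trees"]), table)
        n_tips = trees[0].n_tips
        entry["n_tips"] = n_tips
        if n_tips < min_tips:
            entry.update(eligible=False, reason=f"fewer than {min_tips} tips")
            log.info("clade %s skipped: %s", name, entry["reason"])
            continue
        if len(trees[0].habitats_present()) < 2:
            entry.update(eligible=False, reason="single habitat")
            log.info("clade %s skipped: %s", name, entry["reason"])
            continue
        entry["eligible"] = True
        clade_seed = seed + 1000 * (i + 1)
        post = sample_posterior(
            trees,
            ModelSpace(),
            gens_per_tree=gens,
            burn_in=burn,
            seed=clade_seed,
        )
        entry["posterior"] = post.summary()
        if mt_cfg.get("enabled", True):
            ss = SteppingStoneConfig(
                n_stones=int(mt_cfg.get("n_stones", 20)),
                chain_length=int(mt_cfg.get("chain_length", 1000)),
            )
            z_uneq = stepping_stone(
                trees, ModelSpace(rates="unequal"), cfg=ss, seed=clade_seed + 1
            )
            z_eq = stepping_stone(
                trees, ModelSpace(rates="equal"), cfg=ss, seed=clade_seed + 2
            )
            cmp_ = compare_models(
                z_uneq,
                z_eq,
                threshold=float(mt_cfg.get("threshold", 10.0)),
                label_a="unequal rates",
                label_b="equal rates",
            )
            entry["model_comparison"] = {
                "log_z_unequal": z_uneq.log_z,
                "log_z_unequal_se": z_uneq.se,
                "log_z_equal": z_eq.log_z,
                "log_z_equal_se": z_eq.se,
                "log_bayes_factor": cmp_.log_bayes_factor,
                "verdict": cmp_.verdict,
            }
        if ss_cfg.get("fractions"):
            rows = []
            sub_gens = int(ss_cfg.get("gens_per_tree", max(100, gens // 2)))
            for habitat in ss_cfg.get("habitats", ["marine"]):
                for fraction in ss_cfg["fractions"]:
                    for rep in range(int(ss_cfg.get("replicates", 5))):
                        rep_seed = clade_seed + 7919 * rep + int(1e4 * fraction)
                        try:
                            sub = subsample_tree_set(
                                trees, habitat, float(fraction), rep_seed
                            )
                        except ValueError as exc:
                            rows.append(
                                {
                                    "habitat": habitat,
                                    "fraction": fraction,
                                    "replicate": rep,
                                    "error": str(exc),
                                }
                            )
                            continue
                        sub_post = sample_posterior(
                            sub,
                            ModelSpace(),
                            gens_per_tree=sub_gens,
                            seed=rep_seed,
                        )
                        s = sub_post.summary()
                        rows.append(
                            {
                                "habitat": habitat,
                                "fraction": fraction,
                                "replicate": rep,
                                "q_mn_mean": s["q_mn_mean"],
                                "q_nm_mean": s["q_nm_mean"],
                                "global_rate_mean": s["global_rate_mean"],
                            }
                        )
            entry["sensitivity"] = rows
    if report_path is not None:
        Path(report_path).write_text(json.dumps(report, indent=2))
    return report
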