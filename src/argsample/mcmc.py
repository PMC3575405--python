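"""The Metropolis-Hastings-Green chain over ARGs and model parameters.

A :class:`ChainState` couples the current ARG with scalar parameters
(theta, rho, substitution parameters) and cached log-likelihood /
log-prior values; :func:`step` proposes one kernel move and accepts
with probability min(1, exp((dloglik + dlogprior)/T + log HR)).
Rejected proposals restore the previous state bit-exactly (structure
via the kernel's revert closure, likelihood tables via reference-
swapped stashes).  :func:`run` drives a single chain or a
Metropolis-coupled ladder (sequential, deterministic for a fixed
seed), logs a trace periodically and stores sampled ARGs for the
collectors.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .arg import Arg, annotate_ancestral_material, validate as validate_arg
from .likelihood import Alignment, ArgLikelihood
from .prior import (
    DEFAULT_PRIORS,
    PopulationModel,
    PriorSpec,
    RecombinationModel,
    arg_log_prior,
    parameter_log_prior,
)
from .proposals import ARG_KERNELS, Proposal, propose_scalar
from .simulate import SimulationSpec, simulate_arg
from .substitution import F84, TN93, BaseFrequencies, SubstitutionModel

__all__ = [
    "RunConfig",
    "ChainState",
    "MCMCResult",
    "KernelSet",
    "step",
    "run",
    "mc3_swap",
    "restart_from_best",
]


@dataclass
class RunConfig:
    """Chain settings, model choices and priors for one run.

    ``sample_parameters`` lists the scalars given MCMC moves; anything
    not listed stays fixed at its initial value.  For prior-only runs
    (no alignment) give ``n_tips`` and ``L``.
    """

    chain_length: int
    sample_interval: int = 100
    burn_in_fraction: float = 0.5
    n_chains: int = 1
    temperature_lambda: float = 0.1
    swap_interval: int = 10
    seed: int = 1
    theta: float = 0.01
    rho: float = 1.0
    kappa: float = 2.0
    alpha_r: float = 4.0
    alpha_y: float = 4.0
    substitution_family: str = "F84"
    population: str = "constant"
    growth: float = 0.0
    frequencies: str = "empirical"  # or "uniform"
    sample_parameters: tuple = ("theta", "rho", "kappa")
    kernel_weights: Optional[dict] = None
    priors: Optional[dict] = None
    n_tips: Optional[int] = None
    L: Optional[int] = None
    initial_arg: Optional[dict] = None  # JSON dict, e.g. from restart_from_best
    store_args: bool = True
    arg_sample_interval: Optional[int] = None  # default: sample_interval
    tune: bool = True
    output_prefix: Optional[str] = None

    def validate(self) -> list[str]:
        errs = []
        if self.chain_length < 0:
            errs.append("chain_length must be >= 0")
        if self.sample_interval <= 0:
            errs.append("sample_interval must be positive")
        if not (0.0 <= self.burn_in_fraction < 1.0):
            errs.append("burn_in_fraction must be in [0, 1)")
        if self.n_chains < 1:
            errs.append("n_chains must be >= 1")
        if self.temperature_lambda <= 0 and self.n_chains > 1:
            errs.append("temperature_lambda must be positive for coupled chains")
        if self.theta <= 0:
            errs.append("theta must be positive")
        if self.rho < 0:
            errs.append("rho must be nonnegative")
        if self.substitution_family not in ("F84", "TN93"):
            errs.append(f"unknown substitution family {self.substitution_family!r}")
        if self.population not in ("constant", "exponential_growth"):
            errs.append(f"unknown population model {self.population!r}")
        if self.frequencies not in ("empirical", "uniform"):
            errs.append(f"unknown frequencies mode {self.frequencies!r}")
        for p in self.sample_parameters:
            if p not in ("theta", "rho", "kappa", "alpha_r", "alpha_y"):
                errs.append(f"unknown sampled parameter {p!r}")
        return errs

    def to_json(self) -> str:
        d = asdict(self)
        if d.get("priors"):
            d["priors"] = {k: asdict(v) for k, v in self.priors.items()}
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, s: str) -> "RunConfig":
        d = json.loads(s)
        if d.get("priors"):
            d["priors"] = {k: PriorSpec(**v) for k, v in d["priors"].items()}
        if d.get("sample_parameters") is not None:
            d["sample_parameters"] = tuple(d["sample_parameters"])
        return cls(**d)


def _build_model(config: RunConfig, params: dict,
                 freqs: BaseFrequencies) -> SubstitutionModel:
    if config.substitution_family == "F84":
        return F84(params["kappa"], freqs)
    return TN93(params["alpha_r"], params["alpha_y"], freqs)


@dataclass
class ChainState:
    """Current ARG + parameters + cached log densities for one chain."""

    arg: Arg
    params: dict
    model: SubstitutionModel
    config: RunConfig
    lik: Optional[ArgLikelihood]
    log_lik: float
    log_prior: float
    temperature: float = 1.0
    step_count: int = 0

    def population_model(self) -> PopulationModel:
        return PopulationModel(
            self.params["theta"], self.config.growth, self.config.population
        )

    def recombination_model(self) -> RecombinationModel:
        return RecombinationModel(self.params["rho"])

    def compute_log_prior(self) -> float:
        p = arg_log_prior(
            self.arg, self.population_model(), self.recombination_model()
        )
        sampled = {k: self.params[k] for k in self.config.sample_parameters}
        return p + parameter_log_prior(sampled, self.config.priors or DEFAULT_PRIORS)

    def log_posterior(self) -> float:
        return self.log_lik + self.log_prior

    def audit(self, tol: float = 1e-9) -> None:
        """Verify cached values against from-scratch recomputation."""
        lp = self.compute_log_prior()
        if not math.isclose(lp, self.log_prior, abs_tol=tol, rel_tol=tol):
            raise AssertionError(f"prior cache drift: {lp} vs {self.log_prior}")
        if self.lik is not None:
            ll = ArgLikelihood(self.arg, self.lik.alignment, self.model).recompute()
            if not math.isclose(ll, self.log_lik, abs_tol=tol, rel_tol=tol):
                raise AssertionError(f"likelihood cache drift: {ll} vs {self.log_lik}")


class KernelSet:
    """Kernel mixture with per-kernel tuning scales and acceptance
    accounting.  Scales adapt toward ~23% acceptance during burn-in
    only and are frozen afterwards (detailed balance holds after
    freezing)."""

    TARGET_RATE = 0.234

    def __init__(self, config: RunConfig, scalar_params: tuple,
                 theta_scale: float):
        weights = dict.fromkeys(ARG_KERNELS, 1.0)
        for p in scalar_params:
            weights[f"scale_{p}"] = 0.5
        if config.kernel_weights:
            weights.update(config.kernel_weights)
        self.names = [k for k, w in weights.items() if w > 0]
        w = np.array([weights[k] for k in self.names], dtype=float)
        self.probs = w / w.sum()
        self._cum = np.cumsum(self.probs)
        self.scales = {
            "node_height": 0.3 * theta_scale,
            "root_scale": 0.7,
            "subtree_regraft": 0.0,
            "add_recombination": 2.0,
            "remove_recombination": 2.0,
            "breakpoint_shift": 50,
            "arg_scale": 0.15,
        }
        for p in scalar_params:
            self.scales[f"scale_{p}"] = 0.5
        self.proposed = dict.fromkeys(self.names, 0)
        self.accepted = dict.fromkeys(self.names, 0)
        self.tuning_active = bool(config.tune)
        self._since_tune = dict.fromkeys(self.names, 0)
        self._accept_since = dict.fromkeys(self.names, 0)

    def choose(self, rng) -> str:
        i = int(np.searchsorted(self._cum, rng.uniform()))
        return self.names[min(i, len(self.names) - 1)]

    def record(self, name: str, accepted: bool) -> None:
        self.proposed[name] += 1
        self._since_tune[name] += 1
        if accepted:
            self.accepted[name] += 1
            self._accept_since[name] += 1
        if self.tuning_active and self._since_tune[name] >= 50:
            rate = self._accept_since[name] / self._since_tune[name]
            self._since_tune[name] = 0
            self._accept_since[name] = 0
            if name in ("node_height", "breakpoint_shift", "root_scale",
                        "arg_scale") or name.startswith("scale_"):
                factor = 1.25 if rate > self.TARGET_RATE else 0.8
                s = self.scales[name] * factor
                if name == "breakpoint_shift":
                    self.scales[name] = int(min(max(s, 1), 10_000))
                else:
                    self.scales[name] = min(max(s, 1e-6), 50.0)

    def freeze(self) -> None:
        self.tuning_active = False

    def acceptance_rates(self) -> dict:
        return {
            k: (self.accepted[k] / self.proposed[k]) if self.proposed[k] else float("nan")
            for k in self.names
        }


def _propose(state: ChainState, name: str, kernels: KernelSet, rng) -> Proposal:
    if name.startswith("scale_"):
        return propose_scalar(
            state.params, name[len("scale_"):], rng, kernels.scales[name]
        )
    fn, needs_theta = ARG_KERNELS[name]
    if needs_theta:
        return fn(state.arg, rng, state.params["theta"], kernels.scales[name])
    if name == "subtree_regraft":
        return fn(state.arg, rng)
    return fn(state.arg, rng, kernels.scales[name])


def step(state: ChainState, kernels: KernelSet, rng) -> tuple[ChainState, bool]:
    """One Metropolis-Hastings-Green step; returns (state, accepted)."""
    name = kernels.choose(rng)
    proposal = _propose(state, name, kernels, rng)
    state.step_count += 1
    if proposal.auto_reject:
        kernels.record(name, False)
        return state, False

    structural = bool(proposal.dirty) or bool(proposal.removed)
    if structural:
        annotate_ancestral_material(state.arg, seeds=proposal.dirty)
    new_log_prior = state.compute_log_prior()
    if math.isnan(new_log_prior):
        raise FloatingPointError(
            f"NaN log-prior after kernel {name!r} at step {state.step_count}"
        )

    stash = None
    old_model = None
    new_log_lik = state.log_lik
    if state.lik is not None and new_log_prior != float("-inf"):
        if proposal.params_dirty:
            old_model = state.model
            state.model = old_model.with_parameters(**{
                proposal.param[0]: proposal.param[2]
            })
            state.lik.model = state.model
            new_log_lik, stash = state.lik.update(list(state.arg.nodes))
        elif structural:
            new_log_lik, stash = state.lik.update(proposal.dirty)
        if math.isnan(new_log_lik):
            raise FloatingPointError(
                f"NaN log-likelihood after kernel {name!r} at step {state.step_count}"
            )

    if new_log_prior == float("-inf"):
        log_alpha = float("-inf")
    else:
        log_alpha = (
            (new_log_lik - state.log_lik + new_log_prior - state.log_prior)
            / state.temperature
            + proposal.log_hastings
        )
    accept = log_alpha >= 0 or math.log(rng.uniform()) < log_alpha

    if accept:
        state.log_prior = new_log_prior
        state.log_lik = new_log_lik
        if state.lik is not None and proposal.removed:
            state.lik.drop_nodes(proposal.removed)
    else:
        proposal.revert()
        if old_model is not None:
            state.model = old_model
            if state.lik is not None:
                state.lik.model = old_model
        if structural:
            # revert may re-create removed nodes; refresh them too
            annotate_ancestral_material(
                state.arg, seeds=proposal.dirty + proposal.removed)
        if stash is not None:
            state.lik.restore(stash)
    kernels.record(name, accept)
    return state, accept


def mc3_swap(chains: list[ChainState], rng) -> list[ChainState]:
    """Propose one adjacent-temperature state exchange (no-op for a
    single chain).  States swap while temperatures stay in place; only
    the cold chain (T=1) is ever sampled."""
    if len(chains) < 2:
        return chains
    i = int(rng.integers(len(chains) - 1))
    a, b = chains[i], chains[i + 1]
    log_ratio = (1.0 / a.temperature - 1.0 / b.temperature) * (
        b.log_posterior() - a.log_posterior()
    )
    if log_ratio >= 0 or math.log(rng.uniform()) < log_ratio:
        a.temperature, b.temperature = b.temperature, a.temperature
        chains[i], chains[i + 1] = b, a
    return chains


@dataclass
class MCMCResult:
    trace: pd.DataFrame
    sampled_args: list[dict]
    sampled_arg_steps: list[int]
    best_arg: Optional[dict]
    best_step: Optional[int]
    best_log_posterior: float
    acceptance_rates: dict
    config: RunConfig
    convergence: dict

    def posterior_interval(self, column: str, level: float = 0.95,
                           burn_in: Optional[float] = None) -> tuple[float, float]:
        frac = self.config.burn_in_fraction if burn_in is None else burn_in
        t = self.trace[self.trace["step"] >= frac * self.config.chain_length]
        lo = (1.0 - level) / 2.0
        return (
            float(t[column].quantile(lo)),
            float(t[column].quantile(1.0 - lo)),
        )


def _initial_state(config: RunConfig, alignment: Optional[Alignment],
                   rng) -> ChainState:
    params = {
        "theta": config.theta,
        "rho": config.rho,
        "kappa": config.kappa,
        "alpha_r": config.alpha_r,
        "alpha_y": config.alpha_y,
    }
    if alignment is not None:
        n, L = alignment.n_seqs, alignment.L
        freqs = (
            alignment.empirical_frequencies()
            if config.frequencies == "empirical"
            else BaseFrequencies.uniform()
        )
        if "theta" in config.sample_parameters:
            # Watterson's estimate as a data-informed starting point
            variable = (alignment.patterns.min(axis=0)
                        != alignment.patterns.max(axis=0))
            seg = int(variable @ alignment.pattern_counts)
            a_n = sum(1.0 / i for i in range(1, n))
            if seg > 0:
                params["theta"] = seg / (a_n * L)
    else:
        if config.n_tips is None or config.L is None:
            raise ValueError("prior-only run needs n_tips and L in the config")
        n, L = config.n_tips, config.L
        freqs = BaseFrequencies.uniform()
    model = _build_model(config, params, freqs)
    if config.initial_arg is not None:
        arg = Arg.from_json_dict(config.initial_arg)
        if arg.L != L:
            raise ValueError("initial ARG length does not match data")
    else:
        start_spec = SimulationSpec(n=n, L=L, theta=params["theta"], rho=0.0)
        arg = simulate_arg(start_spec, rng)
    if alignment is not None:
        for nid, name in zip(sorted(arg.tip_labels), alignment.names):
            arg.tip_labels[nid] = name
    annotate_ancestral_material(arg)
    problems = validate_arg(arg)
    if problems:
        raise ValueError(f"invalid starting ARG: {problems[:3]}")
    lik = ArgLikelihood(arg, alignment, model) if alignment is not None else None
    state = ChainState(
        arg=arg, params=params, model=model, config=config, lik=lik,
        log_lik=lik.recompute() if lik is not None else 0.0,
        log_prior=0.0,
    )
    state.log_prior = state.compute_log_prior()
    if state.log_prior == float("-inf"):
        raise ValueError("starting ARG has zero prior density")
    return state


_TRACE_COLUMNS = (
    "step", "log_likelihood", "log_prior", "theta", "rho",
    "kappa", "alpha_r", "alpha_y", "n_recombinations", "root_height",
)


def run(config: RunConfig, alignment: Optional[Alignment] = None,
        arg_callback=None) -> MCMCResult:
    """Execute the chain; returns the trace plus sampled ARGs.

    All randomness flows from ``config.seed``; a fixed seed gives a
    bit-identical trace.  With ``n_chains > 1`` a Metropolis-coupled
    ladder with geometric temperatures T_i = (1+lambda)^(i-1) is run
    sequentially and only the cold chain is sampled.  ``arg_callback``
    (if given) receives every sampled cold-chain ARG for streaming
    collectors.
    """
    errs = config.validate()
    if errs:
        raise ValueError("invalid run config: " + "; ".join(errs))
    rng = np.random.default_rng(config.seed)
    chains = []
    for i in range(config.n_chains):
        st = _initial_state(config, alignment, rng)
        st.temperature = (1.0 + config.temperature_lambda) ** i
        chains.append(st)
    if alignment is not None:
        scalar_params = tuple(config.sample_parameters)
    else:
        # without data only theta/rho have any effect on the target
        scalar_params = tuple(
            p for p in config.sample_parameters if p in ("theta", "rho")
        )
    kernelsets = [
        KernelSet(config, scalar_params, chains[0].params["theta"])
        for _ in chains
    ]

    burn_in_steps = int(config.burn_in_fraction * config.chain_length)
    arg_interval = config.arg_sample_interval or config.sample_interval
    rows = []
    sampled_args: list[dict] = []
    sampled_arg_steps: list[int] = []
    best = (float("-inf"), None, None)

    def cold() -> ChainState:
        for ch in chains:
            if ch.temperature == 1.0:
                return ch
        return chains[0]

    def sample_row(s: ChainState, at_step: int):
        rows.append((
            at_step, s.log_lik, s.log_prior, s.params["theta"], s.params["rho"],
            s.params["kappa"], s.params["alpha_r"], s.params["alpha_y"],
            len(s.arg.recombination_nodes()), s.arg.root.height,
        ))

    frozen = not config.tune
    for it in range(1, config.chain_length + 1):
        if not frozen and it > burn_in_steps:
            for ks in kernelsets:
                ks.freeze()
            frozen = True
        for ch, ks in zip(chains, kernelsets):
            step(ch, ks, rng)
        if config.n_chains > 1 and it % config.swap_interval == 0:
            mc3_swap(chains, rng)
        if it % config.sample_interval == 0:
            s = cold()
            sample_row(s, it)
            lp = s.log_posterior()
            if lp > best[0]:
                best = (lp, s.arg.to_json_dict(), it)
            if it % arg_interval == 0 and it > burn_in_steps:
                if config.store_args:
                    sampled_args.append(s.arg.to_json_dict())
                    sampled_arg_steps.append(it)
                if arg_callback is not None:
                    arg_callback(s.arg, it)

    trace = pd.DataFrame(rows, columns=_TRACE_COLUMNS)
    result = MCMCResult(
        trace=trace,
        sampled_args=sampled_args,
        sampled_arg_steps=sampled_arg_steps,
        best_arg=best[1],
        best_step=best[2],
        best_log_posterior=best[0],
        acceptance_rates=kernelsets[0].acceptance_rates(),
        config=config,
        convergence=convergence_report(trace, config),
    )
    if config.output_prefix:
        write_outputs(result, config.output_prefix)
    return result


def convergence_report(trace: pd.DataFrame, config: RunConfig) -> dict:
    """Advisory check: means and standard deviations of the data
    likelihood compared between adjacent quartiles of the post-burn-in
    trace.  Never stops a run."""
    post = trace[trace["step"] > config.burn_in_fraction * config.chain_length]
    if len(post) < 8:
        return {"assessed": False}
    col = "log_likelihood" if post["log_likelihood"].abs().sum() > 0 else "log_prior"
    quartiles = np.array_split(post[col].to_numpy(), 4)
    means = [float(np.mean(q)) for q in quartiles]
    sds = [float(np.std(q)) for q in quartiles]
    drift = max(
        abs(means[i + 1] - means[i]) / (sds[i] + 1e-12) for i in range(3)
    )
    return {
        "assessed": True,
        "statistic": col,
        "quartile_means": means,
        "quartile_sds": sds,
        "max_mean_shift_in_sd": drift,
        "converged_hint": bool(drift < 0.5),
    }


def restart_from_best(result: MCMCResult) -> RunConfig:
    """Config for a follow-up run seeded at the maximum-posterior ARG
    found so far (ties broken toward the earliest step)."""
    if result.best_arg is None:
        raise ValueError("run stored no ARGs; nothing to restart from")
    d = asdict(result.config)
    if d.get("priors"):
        d["priors"] = result.config.priors
    d["sample_parameters"] = tuple(d["sample_parameters"])
    cfg = RunConfig(**d)
    cfg.initial_arg = result.best_arg
    return cfg


def write_outputs(result: MCMCResult, prefix: str) -> None:
    """Trace TSV, run metadata JSON and sampled-ARG JSON files."""
    result.trace.to_csv(f"{prefix}.trace.tsv", sep="\t", index=False)
    meta = {
        "seed": result.config.seed,
        "chain_length": result.config.chain_length,
        "acceptance_rates": result.acceptance_rates,
        "best_step": result.best_step,
        "best_log_posterior": result.best_log_posterior,
        "convergence": result.convergence,
        "config": json.loads(result.config.to_json()),
    }
    with open(f"{prefix}.meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    with open(f"{prefix}.args.json", "w") as fh:
        json.dump(
            {"steps": result.sampled_arg_steps, "args": result.sampled_args}, fh
        )
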