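"""Coalescent-with-recombination log-density of an ARG, plus parameter priors.

Time is measured in expected substitutions per site.  Backward in time,
with ``k`` extant lineages and population function theta(t):

* total coalescence rate        k (k-1) / theta(t)   (2/theta per pair),
* per-lineage recombination rate (rho / theta0) * g_i / (L - 1),

where ``g_i`` is the number of eligible breakpoint gaps on lineage i:
gaps strictly inside the lineage's [leftmost, rightmost] ancestral site
(Hudson-style; recombinations outside ancestral material are invisible
to the data and carry zero rate by default).  The density of a specific
coalescence event is 2/theta(t) and of a specific recombination event
(lineage, gap) is rho / (theta0 (L-1)).  The backward simulator in
:mod:`argsample.simulate` draws from exactly this density, so the two
are mutually consistent by construction.

Exponential growth uses theta(t) = theta0 * exp(-g t) with the
integrated rate in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .arg import Arg, COALESCENT, RECOMBINATION, TIP, interval_span_gaps

__all__ = [
    "PopulationModel",
    "RecombinationModel",
    "arg_log_prior",
    "parameter_log_prior",
    "PriorSpec",
]


@dataclass(frozen=True)
class PopulationModel:
    """Scaled population size theta(t) = theta0 * exp(-growth * t);
    theta0 = 2 N mu at sampling time, growth in 1/time units
    (0 = constant size)."""

    theta0: float
    growth: float = 0.0
    kind: str = "constant"

    def __post_init__(self):
        if self.theta0 <= 0:
            raise ValueError("theta0 must be positive")
        if self.kind not in ("constant", "exponential_growth"):
            raise ValueError(f"unknown population model kind {self.kind!r}")
        if self.kind == "constant" and self.growth != 0.0:
            raise ValueError("constant model requires growth = 0")

    def theta_at(self, t: float) -> float:
        if self.growth == 0.0:
            return self.theta0
        return self.theta0 * math.exp(-self.growth * t)

    def inverse_theta_integral(self, t0: float, t1: float) -> float:
        """integral_{t0}^{t1} dt / theta(t), closed form."""
        if self.growth == 0.0:
            return (t1 - t0) / self.theta0
        g = self.growth
        return (math.exp(g * t1) - math.exp(g * t0)) / (g * self.theta0)


@dataclass(frozen=True)
class RecombinationModel:
    """Scaled recombination rate rho = 2 N r, constant across sites and
    over time."""

    rho: float

    def __post_init__(self):
        if self.rho < 0:
            raise ValueError("rho must be nonnegative")


def arg_log_prior(arg: Arg, pop: PopulationModel, rec: RecombinationModel) -> float:
    """Natural-log density of the ARG under the neutral coalescent with
    recombination.  Requires an annotated ARG.  Returns -inf for ARGs
    the model cannot produce (a recombination with rho = 0, or a
    breakpoint outside its lineage's eligible gaps)."""
    L = arg.L
    gaps_denom = L - 1
    # active lineages: (child_node_id, slot) -> eligible gap count
    active: dict[tuple[int, int], int] = {}
    for tip in arg.tips():
        if tip.ancestral_material is None:
            raise ValueError("ARG is not annotated; call annotate_ancestral_material")
        active[(tip.id, 0)] = interval_span_gaps(tip.ancestral_material)
    rec_unit = rec.rho / pop.theta0 / gaps_denom if gaps_denom > 0 else 0.0
    logp = 0.0
    t_prev = 0.0
    for node in arg.nodes_ascending():
        if node.kind == TIP:
            continue
        t = node.height
        k = len(active)
        if k < 2:
            # events above the grand MRCA: the backward process stops
            # when one lineage remains, so such ARGs have zero density
            return float("-inf")
        total_gaps = sum(active.values())
        # survival over (t_prev, t]
        logp -= k * (k - 1) * pop.inverse_theta_integral(t_prev, t)
        logp -= rec_unit * total_gaps * (t - t_prev)
        incoming = arg.incoming_edges(node)
        if node.kind == COALESCENT:
            logp += math.log(2.0 / pop.theta_at(t))
            for c, j in incoming:
                active.pop((c.id, j))
            active[(node.id, 0)] = interval_span_gaps(node.ancestral_material)
        elif node.kind == RECOMBINATION:
            (child_edge,) = incoming
            c, j = child_edge
            m = node.ancestral_material
            b = node.breakpoint
            eligible = bool(m) and (m[0].start < b <= m[-1].end - 1)
            if rec.rho == 0.0 or rec_unit == 0.0 or not eligible:
                return float("-inf")
            logp += math.log(rec_unit)
            active.pop((c.id, j))
            active[(node.id, 0)] = interval_span_gaps(
                arg.edge_material(node, 0)
            )
            active[(node.id, 1)] = interval_span_gaps(
                arg.edge_material(node, 1)
            )
        t_prev = t
    if len(active) != 1:
        raise ValueError("event sweep did not end with a single lineage")
    return logp


# ---------------------------------------------------------------------------
# scalar parameter priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Independent prior on one scalar parameter.

    ``dist`` is ``log_uniform`` (Jeffreys-like, density 1/(x ln(hi/lo)))
    or ``uniform`` on [low, high]."""

    dist: str
    low: float
    high: float

    def __post_init__(self):
        if self.dist not in ("uniform", "log_uniform"):
            raise ValueError(f"unknown prior {self.dist!r}")
        if not (self.low < self.high):
            raise ValueError("need low < high")
        if self.dist == "log_uniform" and self.low <= 0:
            raise ValueError("log_uniform needs a positive lower bound")

    def log_density(self, x: float) -> float:
        if not (self.low <= x <= self.high):
            return float("-inf")
        if self.dist == "uniform":
            return -math.log(self.high - self.low)
        return -math.log(x) - math.log(math.log(self.high / self.low))


DEFAULT_PRIORS = {
    "theta": PriorSpec("log_uniform", 1e-6, 10.0),
    "rho": PriorSpec("log_uniform", 1e-3, 100.0),
    "kappa": PriorSpec("uniform", 0.0, 100.0),
    "alpha_r": PriorSpec("log_uniform", 1e-3, 100.0),
    "alpha_y": PriorSpec("log_uniform", 1e-3, 100.0),
}


def parameter_log_prior(params: dict[str, float],
                        priors: dict[str, PriorSpec] | None = None) -> float:
    """Sum of independent log prior densities for the scalar parameters
    present in ``params``; -inf outside support."""
    priors = priors or DEFAULT_PRIORS
    total = 0.0
    for name, value in params.items():
        spec = priors.get(name)
        if spec is None:
            continue
        total += spec.log_density(value)
    return total
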