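"""Demographic model family for the two-ricefish introgression test.

Two diploid populations are modelled backward in time: population 1 is the
focal/recipient species (*O. sarasinorum*-like, large current size) and
population 2 the putative donor (*O. eversi*-like).  Each population is
constant at its current size back to a change-onset time TCHG, then changes
exponentially to its size at the divergence time, and the two lineages join
into a common ancestor of size NANC1 at TDIV1.  On top of this shared
"allopatric divergence" core (ALD) the family adds:

* DGF  — continuous gene flow between the two populations until TDIV1,
* ADM1 — a single admixture pulse at TAD: looking backward, each focal
  lineage relocates to the donor with probability ADMIX,
* ADM2 — the same pulse, but the source is an unsampled ("ghost")
  population that split from the donor's lineage at TDIV2.

Five one-population size-change models (CONST, RECENT_GROWTH,
RECENT_DECLINE, PASTGROWTH, BOTTLENECK) are provided for per-species model
screening before the two-population comparison.

Times are generations before present (t = 0 at sampling); sizes are diploid
individuals.  Growth is exponential between epoch boundaries, never linear.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "ONE_POP_MODELS",
    "TWO_POP_MODELS",
    "MODEL_FREE_PARAMS",
    "Event",
    "Demography",
    "ModelSpec",
    "build_one_pop_model",
    "build_two_pop_model",
    "build_model",
    "population_size_at",
    "count_free_parameters",
    "ParamBounds",
]

ONE_POP_MODELS = ("CONST", "RECENT_GROWTH", "RECENT_DECLINE", "PASTGROWTH", "BOTTLENECK")
TWO_POP_MODELS = ("ALD", "DGF", "ADM1", "ADM2")

_ALD_PARAMS = ("NPOP1", "NPOP2", "NDIV11", "NDIV12", "NANC1", "TCHG1", "TCHG2", "TDIV1")

#: Free parameters of every model, in canonical order.
MODEL_FREE_PARAMS: dict[str, tuple[str, ...]] = {
    "CONST": ("NPOP",),
    "RECENT_GROWTH": ("NPOP", "NANC", "TCHG"),
    "RECENT_DECLINE": ("NPOP", "NANC", "TCHG"),
    "PASTGROWTH": ("NPOP", "NANC", "TCHG1", "TCHG2"),
    "BOTTLENECK": ("NPOP", "NBOT", "TCHG1", "TCHG2"),
    "ALD": _ALD_PARAMS,
    "DGF": _ALD_PARAMS + ("MIG12", "MIG21"),
    "ADM1": _ALD_PARAMS + ("TAD", "ADMIX"),
    "ADM2": _ALD_PARAMS + ("TAD", "ADMIX", "NPOP3", "NDIV13", "TCHG3", "TDIV2", "NANC2"),
}

_SIZE_PARAMS = frozenset(
    {"NPOP", "NANC", "NBOT", "NPOP1", "NPOP2", "NPOP3",
     "NDIV11", "NDIV12", "NDIV13", "NANC1", "NANC2"}
)
_TIME_PARAMS = frozenset({"TCHG", "TCHG1", "TCHG2", "TCHG3", "TDIV1", "TDIV2", "TAD"})

PULSE = 0
JOIN = 1

#: sentinel for "infinitely old" in compiled epoch tables
T_INF = 1.0e300


class ModelValidationError(ValueError):
    """Raised when a parameter set violates a model's constraints."""


@dataclass(frozen=True)
class Event:
    """A discrete backward-in-time event at an epoch boundary.

    kind PULSE: each lineage in ``src`` moves to ``dst`` with probability
    ``prob``; kind JOIN: all lineages in ``src`` move to ``dst``.
    """

    time: float
    kind: int
    src: int
    dst: int
    prob: float = 1.0

    @property
    def kind_name(self) -> str:
        return "pulse" if self.kind == PULSE else "join"


@dataclass
class Demography:
    """Compiled piecewise-exponential demography, kernel-ready.

    Within epoch ``e`` (times ``breaks[e] <= t < breaks[e+1]``) population
    ``p`` has diploid size ``N0[e, p] * exp(beta[e, p] * (t - breaks[e]))``
    and per-lineage backward migration rates ``mig[e, p, q]``.
    """

    breaks: np.ndarray          # (n_epochs + 1,), breaks[0]=0, breaks[-1]=T_INF
    N0: np.ndarray              # (n_epochs, n_pops)
    beta: np.ndarray            # (n_epochs, n_pops)
    mig: np.ndarray             # (n_epochs, n_pops, n_pops)
    ev_bidx: np.ndarray         # boundary index of each event (into breaks)
    ev_kind: np.ndarray
    ev_src: np.ndarray
    ev_dst: np.ndarray
    ev_prob: np.ndarray

    @property
    def n_pops(self) -> int:
        return self.N0.shape[1]

    def as_tuple(self):
        return (self.breaks, self.N0, self.beta, self.mig,
                self.ev_bidx, self.ev_kind, self.ev_src, self.ev_dst, self.ev_prob)


# segment: (t0, t1, n_start, n_end); exponential interpolation inside
_Segment = tuple[float, float, float, float]


@dataclass
class ModelSpec:
    """A validated demographic model: name, parameter values, event schedule."""

    name: str
    params: dict[str, float]
    populations: tuple[str, ...] = ()
    free_parameters: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if not self.free_parameters:
            self.free_parameters = MODEL_FREE_PARAMS[self.name]
        if not self.populations:
            if self.name in ONE_POP_MODELS:
                self.populations = ("pop1",)
            else:
                self.populations = ("pop1", "pop2")
        self._validate()

    # -- validation -------------------------------------------------------
    def _validate(self) -> None:
        if self.name not in MODEL_FREE_PARAMS:
            raise ModelValidationError(f"unknown model name {self.name!r}")
        required = set(MODEL_FREE_PARAMS[self.name])
        given = set(self.params)
        if given != required:
            missing = sorted(required - given)
            extra = sorted(given - required)
            raise ModelValidationError(
                f"{self.name}: missing parameters {missing}, unexpected {extra}")
        p = self.params
        for name, val in p.items():
            if not math.isfinite(val):
                raise ModelValidationError(f"{name} must be finite, got {val}")
            if name in _SIZE_PARAMS and val <= 0:
                raise ModelValidationError(f"size {name} must be > 0, got {val}")
            if name in _TIME_PARAMS and val < 0:
                raise ModelValidationError(f"time {name} must be >= 0, got {val}")
            if name in ("MIG12", "MIG21") and val < 0:
                raise ModelValidationError(f"migration rate {name} must be >= 0")
        if "ADMIX" in p and not (0.0 <= p["ADMIX"] <= 1.0):
            raise ModelValidationError(f"ADMIX must be in [0, 1], got {p['ADMIX']}")
        n = self.name
        if n in ("RECENT_GROWTH", "RECENT_DECLINE"):
            if n == "RECENT_GROWTH" and p["NPOP"] < p["NANC"]:
                raise ModelValidationError("RECENT_GROWTH requires NPOP >= NANC")
            if n == "RECENT_DECLINE" and p["NPOP"] > p["NANC"]:
                raise ModelValidationError("RECENT_DECLINE requires NPOP <= NANC")
        if n in ("PASTGROWTH", "BOTTLENECK") and p["TCHG1"] > p["TCHG2"]:
            raise ModelValidationError(f"{n} requires TCHG1 <= TCHG2")
        if n in TWO_POP_MODELS:
            if p["TCHG1"] > p["TDIV1"]:
                raise ModelValidationError("TCHG1 must be <= TDIV1")
            tdiv_pop2 = p["TDIV2"] if n == "ADM2" else p["TDIV1"]
            if p["TCHG2"] > tdiv_pop2:
                raise ModelValidationError("TCHG2 exceeds population 2's divergence time")
        if n in ("ADM1", "ADM2"):
            tad_upper = p["TDIV2"] if n == "ADM2" else p["TDIV1"]
            if not p["TAD"] < tad_upper:
                raise ModelValidationError("TAD must precede the relevant divergence time")
        if n == "ADM2":
            if not p["TDIV2"] < p["TDIV1"]:
                raise ModelValidationError("ADM2 requires TAD < TDIV2 < TDIV1")
            if p["TCHG3"] > p["TDIV2"]:
                raise ModelValidationError("TCHG3 must be <= TDIV2")

    # -- size trajectories ------------------------------------------------
    def _segments(self) -> list[list[_Segment]]:
        """Per-population piecewise-exponential size segments (backward time)."""
        p = self.params
        n = self.name
        if n == "CONST":
            return [[(0.0, math.inf, p["NPOP"], p["NPOP"])]]
        if n in ("RECENT_GROWTH", "RECENT_DECLINE"):
            return [[(0.0, p["TCHG"], p["NPOP"], p["NANC"]),
                     (p["TCHG"], math.inf, p["NANC"], p["NANC"])]]
        if n == "PASTGROWTH":
            return [[(0.0, p["TCHG1"], p["NPOP"], p["NPOP"]),
                     (p["TCHG1"], p["TCHG2"], p["NPOP"], p["NANC"]),
                     (p["TCHG2"], math.inf, p["NANC"], p["NANC"])]]
        if n == "BOTTLENECK":
            return [[(0.0, p["TCHG1"], p["NPOP"], p["NPOP"]),
                     (p["TCHG1"], p["TCHG2"], p["NBOT"], p["NBOT"]),
                     (p["TCHG2"], math.inf, p["NPOP"], p["NPOP"])]]
        # two-population core
        pop1 = [(0.0, p["TCHG1"], p["NPOP1"], p["NPOP1"]),
                (p["TCHG1"], p["TDIV1"], p["NPOP1"], p["NDIV11"]),
                (p["TDIV1"], math.inf, p["NANC1"], p["NANC1"])]
        if n == "ADM2":
            pop2 = [(0.0, p["TCHG2"], p["NPOP2"], p["NPOP2"]),
                    (p["TCHG2"], p["TDIV2"], p["NPOP2"], p["NDIV12"]),
                    (p["TDIV2"], p["TDIV1"], p["NANC2"], p["NANC2"]),
                    (p["TDIV1"], math.inf, p["NANC1"], p["NANC1"])]
            ghost = [(0.0, p["TCHG3"], p["NPOP3"], p["NPOP3"]),
                     (p["TCHG3"], p["TDIV2"], p["NPOP3"], p["NDIV13"]),
                     (p["TDIV2"], math.inf, p["NANC2"], p["NANC2"])]
            return [pop1, pop2, ghost]
        pop2 = [(0.0, p["TCHG2"], p["NPOP2"], p["NPOP2"]),
                (p["TCHG2"], p["TDIV1"], p["NPOP2"], p["NDIV12"]),
                (p["TDIV1"], math.inf, p["NANC1"], p["NANC1"])]
        return [pop1, pop2]

    def size_at(self, pop: int, t: float) -> float:
        """Diploid size of population ``pop`` (0-based) at ``t`` generations ago.

        Exponential interpolation within a change epoch:
        ``N(t) = Nstart * (Nend/Nstart) ** ((t - t0) / (t1 - t0))``.
        Epoch-boundary times take the value of the younger (smaller-t) epoch's
        endpoint, so ``size_at(0, TDIV1)`` returns NDIV11, not NANC1.
        """
        if t < 0:
            raise ValueError(f"t must be >= 0, got {t}")
        segs = self._segments()
        if not 0 <= pop < len(segs):
            raise ValueError(f"invalid population index {pop} for {self.name}")
        for t0, t1, n_start, n_end in segs[pop]:
            if t0 <= t <= t1:
                if t1 == math.inf or n_start == n_end or t1 == t0:
                    return n_start
                frac = (t - t0) / (t1 - t0)
                return n_start * (n_end / n_start) ** frac
        raise AssertionError("unreachable: segments cover [0, inf)")

    # -- events -----------------------------------------------------------
    def event_schedule(self) -> list[Event]:
        """Backward-in-time discrete events, strictly ordered by time."""
        p = self.params
        n = self.name
        events: list[Event] = []
        if n == "ALD" or n == "DGF":
            events.append(Event(p["TDIV1"], JOIN, 1, 0))
        elif n == "ADM1":
            events.append(Event(p["TAD"], PULSE, 0, 1, p["ADMIX"]))
            events.append(Event(p["TDIV1"], JOIN, 1, 0))
        elif n == "ADM2":
            events.append(Event(p["TAD"], PULSE, 0, 2, p["ADMIX"]))
            events.append(Event(p["TDIV2"], JOIN, 2, 1))
            events.append(Event(p["TDIV1"], JOIN, 1, 0))
        return sorted(events, key=lambda e: e.time)

    @property
    def n_sampled_pops(self) -> int:
        return 1 if self.name in ONE_POP_MODELS else 2

    # -- compilation ------------------------------------------------------
    def compile(self) -> Demography:
        """Flatten the model into epoch tables for the coalescent kernel."""
        segs = self._segments()
        n_pops = len(segs)
        events = self.event_schedule()
        cut: set[float] = {0.0}
        for pop_segs in segs:
            for t0, t1, _, _ in pop_segs:
                cut.add(t0)
                if t1 != math.inf:
                    cut.add(t1)
        for ev in events:
            cut.add(ev.time)
        times = sorted(cut)
        breaks = np.array(times + [T_INF], dtype=np.float64)
        n_epochs = len(breaks) - 1
        N0 = np.empty((n_epochs, n_pops))
        beta = np.zeros((n_epochs, n_pops))
        for e in range(n_epochs):
            te = breaks[e]
            for pidx, pop_segs in enumerate(segs):
                for t0, t1, n_start, n_end in pop_segs:
                    if t1 == t0:  # degenerate (zero-length) segment
                        continue
                    # segment covering [te, breaks[e+1]); boundaries never split segments
                    if t0 <= te < t1:
                        if t1 == math.inf or n_start == n_end:
                            N0[e, pidx] = n_end
                            beta[e, pidx] = 0.0
                        else:
                            b = math.log(n_end / n_start) / (t1 - t0)
                            N0[e, pidx] = n_start * math.exp(b * (te - t0))
                            beta[e, pidx] = b
                        break
                else:  # te at/after last finite boundary: constant tail
                    N0[e, pidx] = pop_segs[-1][3]
                    beta[e, pidx] = 0.0
        mig = np.zeros((n_epochs, n_pops, n_pops))
        if self.name == "DGF":
            tdiv = self.params["TDIV1"]
            for e in range(n_epochs):
                if breaks[e + 1] <= tdiv:
                    mig[e, 0, 1] = self.params["MIG12"]
                    mig[e, 1, 0] = self.params["MIG21"]
        ev_bidx, ev_kind, ev_src, ev_dst, ev_prob = [], [], [], [], []
        for ev in events:
            b = int(np.searchsorted(breaks, ev.time))
            assert breaks[b] == ev.time
            ev_bidx.append(b)
            ev_kind.append(ev.kind)
            ev_src.append(ev.src)
            ev_dst.append(ev.dst)
            ev_prob.append(ev.prob)
        return Demography(
            breaks=breaks, N0=N0, beta=beta, mig=mig,
            ev_bidx=np.array(ev_bidx, dtype=np.int64),
            ev_kind=np.array(ev_kind, dtype=np.int64),
            ev_src=np.array(ev_src, dtype=np.int64),
            ev_dst=np.array(ev_dst, dtype=np.int64),
            ev_prob=np.array(ev_prob, dtype=np.float64),
        )

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {"name": self.name,
                "populations": list(self.populations),
                "params": {k: float(v) for k, v in self.params.items()}}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(name=d["name"], params=dict(d["params"]),
                   populations=tuple(d.get("populations", ())))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def build_two_pop_model(name: str, params: dict[str, float],
                        populations: tuple[str, str] = ("pop1", "pop2")) -> ModelSpec:
    """Build and validate one of the two-population models ALD/DGF/ADM1/ADM2.

    ``params`` may contain extra entries (e.g. a full shared parameter set);
    only the model's own free parameters are used.
    """
    if name not in TWO_POP_MODELS:
        raise ModelValidationError(f"unknown two-population model {name!r}")
    wanted = MODEL_FREE_PARAMS[name]
    missing = [k for k in wanted if k not in params]
    if missing:
        raise ModelValidationError(f"{name}: missing parameters {missing}")
    return ModelSpec(name=name, params={k: float(params[k]) for k in wanted},
                     populations=populations)


def build_one_pop_model(name: str, params: dict[str, float],
                        population: str = "pop1") -> ModelSpec:
    """Build one of the five one-population size-change models."""
    if name not in ONE_POP_MODELS:
        raise ModelValidationError(f"unknown one-population model {name!r}")
    wanted = MODEL_FREE_PARAMS[name]
    missing = [k for k in wanted if k not in params]
    if missing:
        raise ModelValidationError(f"{name}: missing parameters {missing}")
    return ModelSpec(name=name, params={k: float(params[k]) for k in wanted},
                     populations=(population,))


def build_model(name: str, params: dict[str, float]) -> ModelSpec:
    if name in ONE_POP_MODELS:
        return build_one_pop_model(name, params)
    return build_two_pop_model(name, params)


def population_size_at(model: ModelSpec, pop: int, t: float) -> float:
    """Diploid size of ``pop`` (0-based index) at time ``t`` generations ago."""
    return model.size_at(pop, t)


def count_free_parameters(model: ModelSpec) -> int:
    """Number of free parameters (the AIC ``k`` of the model)."""
    return len(model.free_parameters)


@dataclass
class ParamBounds:
    """Search bounds for one parameter: [low, high] on the given scale.

    scale: 'log10' (sizes, times, rates), 'logit' (proportions) or 'linear'.
    """

    low: float
    high: float
    scale: str = "log10"

    def __post_init__(self):
        if self.low > self.high:
            raise ValueError(f"low > high: {self.low} > {self.high}")
        if self.scale not in ("log10", "linear", "logit"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "log10" and self.low <= 0:
            raise ValueError("log10 scale requires low > 0")
        if self.scale == "logit" and not (0 < self.low and self.high < 1):
            raise ValueError("logit scale requires bounds inside (0, 1)")

    def transform(self, value: float) -> float:
        if self.scale == "log10":
            return math.log10(value)
        if self.scale == "logit":
            return math.log(value / (1.0 - value))
        return value

    def inverse(self, x: float) -> float:
        if self.scale == "log10":
            return 10.0 ** x
        if self.scale == "logit":
            return 1.0 / (1.0 + math.exp(-x))
        return x

    def transformed_interval(self) -> tuple[float, float]:
        return self.transform(self.low), self.transform(self.high)


#: Canonical study-scale parameters of the best-supported two-population
#: model (ADM1) for the ricefish pair: the reported point estimates for the
#: divergence time (85,000 generations), admixture time (7,700) and
#: admixture proportion (2.3%), with sizes/change-times fixed once inside
#: the published 95% intervals (geometric midpoints for the narrow
#: intervals; lower-half values for the very wide size intervals, keeping
#: the synthetic segregating-site count at the study's order of magnitude).
ADM1_STUDY_SCALE: dict[str, float] = {
    "NPOP1": 148_000.0, "NPOP2": 15_400.0,
    "NDIV11": 25_000.0, "NDIV12": 300_000.0, "NANC1": 250_000.0,
    "TCHG1": 26_500.0, "TCHG2": 12_500.0,
    "TDIV1": 85_000.0, "TAD": 7_700.0, "ADMIX": 0.023,
}


def study_search_bounds(name: str, scale: dict[str, float] | None = None,
                        spread: float = 10.0) -> dict[str, ParamBounds]:
    """Search ranges spanning ``spread``-fold around the study-scale
    parameter values (defaults to :data:`ADM1_STUDY_SCALE` for the shared
    parameters) — the desk-scale alternative to the fully broad
    :func:`default_bounds`, which cover four orders of magnitude per
    parameter and need cluster-scale search budgets to explore reliably.
    """
    scale = dict(ADM1_STUDY_SCALE if scale is None else scale)
    base = default_bounds(name)
    out: dict[str, ParamBounds] = {}
    for p, b in base.items():
        v = scale.get(p)
        if v is None or p == "ADMIX":
            out[p] = ParamBounds(1e-3, 0.3, "logit") if p == "ADMIX" else b
        else:
            out[p] = ParamBounds(max(b.low, v / spread),
                                 min(b.high, v * spread), b.scale)
    return out


def default_bounds(name: str) -> dict[str, ParamBounds]:
    """Broad log-uniform search ranges covering the published parameter scale."""
    sizes = ParamBounds(1e2, 5e6, "log10")
    times = ParamBounds(1e2, 1e6, "log10")
    out: dict[str, ParamBounds] = {}
    for p in MODEL_FREE_PARAMS[name]:
        if p in _SIZE_PARAMS:
            out[p] = sizes
        elif p in _TIME_PARAMS:
            out[p] = times
        elif p == "ADMIX":
            out[p] = ParamBounds(1e-4, 0.9, "logit")
        else:  # migration rates
            out[p] = ParamBounds(1e-10, 1e-2, "log10")
    return out
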