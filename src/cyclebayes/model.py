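"""Network variants and ODE right-hand sides for the yeast cyclin model.

The model describes transcriptional regulation of the four cyclins CLN3,
CLN2, CLB5 and CLB2 by the transcription-factor subunits SWI4 (SBF),
NDD1 (Mcm1-Fkh) and SWI5 (Swi/Snf), optionally extended with HCM1 and the
inhibitory factor YOX1.  Every gene is represented by two species, its mRNA
transcript and its protein, both in micromolar; time is in seconds.

Rate equations are mass-action with an optional Hill-repression term:

    dm_i/dt = (beta_i + alpha_i * P_act(i)) * f_inh(i) - deltam * m_i
    dP_i/dt = kappa * m_i - deltap_i * P_i * g_inh(i)

where ``f_inh`` (transcription) and ``g_inh`` (degradation) are
``1 / (1 + (x / K)^h)`` repression factors, equal to 1 when the gene has no
inhibitor.  The mRNA degradation rate ``deltam`` and the translation rate
``kappa`` are shared by all genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "GeneSpec",
    "ModelSpec",
    "ParameterVector",
    "PriorSpec",
    "build_model",
    "build_reduced_model",
    "inhibition_factor",
    "rhs",
    "param_names",
    "pack_log10",
    "unpack_log10",
    "default_prior",
    "DEFAULT_PERIOD",
]

#: Default cell-cycle period: 80 minutes, in seconds.
DEFAULT_PERIOD = 4800.0

VALID_VARIANTS = (1, 2, 3, 4)


class ConfigurationError(ValueError):
    """Raised for invalid model or sampler configuration."""


@dataclass(frozen=True)
class GeneSpec:
    """One gene: its transcriptional activator and optional inhibitors.

    ``activator`` is the gene whose *protein* drives transcription (``None``
    only in reduced benchmark models, where transcription is basal).
    ``transcription_inhibitor`` represses transcription of this gene;
    ``degradation_inhibitor`` inhibits degradation of this gene's protein.
    """

    name: str
    activator: str | None
    transcription_inhibitor: str | None = None
    degradation_inhibitor: str | None = None


@dataclass(frozen=True)
class ModelSpec:
    """A wired network variant plus the cell-cycle period (seconds)."""

    variant: int
    genes: tuple[GeneSpec, ...]
    period: float = DEFAULT_PERIOD

    def __post_init__(self) -> None:
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate gene names in model")
        known = set(names)
        for g in self.genes:
            for ref in (g.activator, g.transcription_inhibitor, g.degradation_inhibitor):
                if ref is not None and ref not in known:
                    raise ConfigurationError(
                        f"gene {g.name!r} references unknown gene {ref!r}"
                    )

    @property
    def gene_names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.genes)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def species(self) -> tuple[str, ...]:
        """All mRNA species followed by all protein species."""
        return tuple(f"mRNA_{g.name}" for g in self.genes) + tuple(
            f"protein_{g.name}" for g in self.genes
        )

    @property
    def n_species(self) -> int:
        return 2 * len(self.genes)

    @property
    def transcription_inhibition_edges(self) -> tuple[tuple[str, str], ...]:
        """(inhibitor, target) pairs for transcription repression."""
        return tuple(
            (g.transcription_inhibitor, g.name)
            for g in self.genes
            if g.transcription_inhibitor is not None
        )

    @property
    def degradation_inhibition_edges(self) -> tuple[tuple[str, str], ...]:
        """(inhibitor, target) pairs for protein-degradation inhibition."""
        return tuple(
            (g.degradation_inhibitor, g.name)
            for g in self.genes
            if g.degradation_inhibitor is not None
        )

    def gene_index(self, name: str) -> int:
        try:
            return self.gene_names.index(name)
        except ValueError:
            raise KeyError(f"gene {name!r} not in model") from None

    @property
    def is_decoupled(self) -> bool:
        """True when every gene is basal-only with no inhibition edges.

        Such models are linear and block-diagonal per gene, so trajectories
        have a closed form (used as a fast path by :mod:`cyclebayes.simulate`).
        """
        return all(
            g.activator is None
            and g.transcription_inhibitor is None
            and g.degradation_inhibitor is None
            for g in self.genes
        )


def build_model(variant: int, period: float = DEFAULT_PERIOD) -> ModelSpec:
    """Construct one of the four nested network variants.

    Variant 1 is the seven-gene core (four cyclins + SWI4, NDD1, SWI5);
    variant 2 inserts HCM1 between SWI4 and NDD1; variant 3 adds YOX1 with
    negative feedback onto SWI4 and CLN3 transcription; variant 4 adds
    inhibition of NDD1 protein degradation by CLN2.
    """
    if variant not in VALID_VARIANTS:
        raise ConfigurationError(
            f"unknown model variant {variant!r}; valid variants are 1, 2, 3, 4"
        )
    has_hcm1 = variant >= 2
    has_yox1 = variant >= 3
    has_ndd1_deg = variant >= 4

    tinh = {"SWI4": "YOX1", "CLN3": "YOX1"} if has_yox1 else {}
    genes = [
        GeneSpec("CLN3", activator="SWI5", transcription_inhibitor=tinh.get("CLN3")),
        GeneSpec("CLN2", activator="SWI4"),
        GeneSpec("CLB5", activator="SWI4"),
        GeneSpec("CLB2", activator="NDD1"),
        GeneSpec("SWI4", activator="CLN3", transcription_inhibitor=tinh.get("SWI4")),
        GeneSpec(
            "NDD1",
            activator="HCM1" if has_hcm1 else "SWI4",
            degradation_inhibitor="CLN2" if has_ndd1_deg else None,
        ),
        GeneSpec("SWI5", activator="NDD1"),
    ]
    if has_hcm1:
        genes.append(GeneSpec("HCM1", activator="SWI4"))
    if has_yox1:
        genes.append(GeneSpec("YOX1", activator="SWI4"))
    return ModelSpec(variant=variant, genes=tuple(genes), period=period)


def build_reduced_model(period: float = DEFAULT_PERIOD) -> ModelSpec:
    """Single-gene benchmark model: basal transcription only, no regulation.

    Linear and analytically solvable; used for sampler benchmarking,
    parameter-recovery and calibration studies.  Tagged ``variant=0``.
    """
    return ModelSpec(variant=0, genes=(GeneSpec("GENE1", activator=None),), period=period)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

def param_names(model: ModelSpec) -> tuple[str, ...]:
    """Canonical parameter ordering for a model.

    Per gene: ``beta_<g>`` (basal transcription, uM/s), ``alpha_<g>``
    (induced transcription, 1/s; absent for basal-only genes),
    ``deltap_<g>`` (protein degradation, 1/s), ``m0_<g>`` and ``p0_<g>``
    (initial concentrations, uM).  Shared: ``deltam`` (mRNA degradation,
    1/s) and ``kappa`` (translation, 1/s).  Per inhibition edge:
    ``K_<target>``/``h_<target>`` (transcription) and ``Kdeg_<target>``/
    ``hdeg_<target>`` (degradation).  Error scales ``sigma_tc``, ``sigma_ss``.
    """
    names: list[str] = []
    for g in model.genes:
        names.append(f"beta_{g.name}")
        if g.activator is not None:
            names.append(f"alpha_{g.name}")
        names.append(f"deltap_{g.name}")
        names.append(f"m0_{g.name}")
        names.append(f"p0_{g.name}")
    names += ["deltam", "kappa"]
    for _, target in model.transcription_inhibition_edges:
        names += [f"K_{target}", f"h_{target}"]
    for _, target in model.degradation_inhibition_edges:
        names += [f"Kdeg_{target}", f"hdeg_{target}"]
    names += ["sigma_tc", "sigma_ss"]
    return tuple(names)


def _linear_mask(names: Iterable[str]) -> np.ndarray:
    """Boolean mask of parameters kept on linear scale (Hill exponents)."""
    return np.array([n.startswith(("h_", "hdeg_")) for n in names], dtype=bool)


@dataclass(frozen=True)
class ParameterVector:
    """Named parameters on sampling scale: log10 except Hill exponents.

    ``values[i]`` is ``log10`` of the linear value unless ``names[i]`` is a
    Hill exponent (``h_*`` / ``hdeg_*``), which stays linear.
    """

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ConfigurationError("duplicate parameter names")
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.names),):
            raise ConfigurationError(
                f"parameter vector length {vals.shape} does not match "
                f"{len(self.names)} names"
            )
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown parameter {name!r}") from None

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.index(name)])

    def to_linear(self) -> dict[str, float]:
        return unpack_log10(self)

    def replace(self, **updates: float) -> "ParameterVector":
        """New vector with some sampling-scale values replaced."""
        vals = self.values.copy()
        for k, v in updates.items():
            vals[self.index(k)] = v
        return ParameterVector(self.names, vals)


def pack_log10(linear: Mapping[str, float], names: Iterable[str] | None = None) -> ParameterVector:
    """Pack linear-scale parameters into a sampling-scale vector.

    Hill exponents pass through unchanged; everything else must be strictly
    positive and is log10-transformed.
    """
    names = tuple(names) if names is not None else tuple(linear.keys())
    mask = _linear_mask(names)
    vals = np.empty(len(names))
    for i, n in enumerate(names):
        x = float(linear[n])
        if x <= 0 or not math.isfinite(x):
            raise ValueError(f"parameter {n!r} must be positive and finite, got {x}")
        vals[i] = x if mask[i] else math.log10(x)
    return ParameterVector(names, vals)


def unpack_log10(pv: ParameterVector) -> dict[str, float]:
    """Inverse of :func:`pack_log10`: sampling scale back to linear."""
    mask = _linear_mask(pv.names)
    out = {}
    for i, n in enumerate(pv.names):
        out[n] = float(pv.values[i]) if mask[i] else float(10.0 ** pv.values[i])
    return out


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

# Default box bounds on sampling scale, by parameter class.  Rates span
# 1e-6..10 (1/s or uM/s), concentrations 1e-5..10 uM, error scales 1e-2..10;
# Hill exponents are linear-uniform on [1, 4].
_DEFAULT_BOUNDS = {
    "rate": (-6.0, 1.0),
    "conc": (-5.0, 1.0),
    "sigma": (-2.0, 1.0),
    "hill": (1.0, 4.0),
}


def _param_class(name: str) -> str:
    if name.startswith(("h_", "hdeg_")):
        return "hill"
    if name.startswith(("m0_", "p0_", "K_", "Kdeg_")):
        return "conc"
    if name.startswith("sigma_"):
        return "sigma"
    return "rate"


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform boxes on sampling scale (log10 except Hill)."""

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        if lo.shape != (len(self.names),) or hi.shape != (len(self.names),):
            raise ConfigurationError("prior bound arrays must match names")
        if not np.all(lo < hi):
            bad = [n for n, a, b in zip(self.names, lo, hi) if not a < b]
            raise ConfigurationError(f"lower >= upper for parameters {bad}")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def contains(self, values: np.ndarray) -> np.ndarray:
        """Elementwise box membership (closed bounds); broadcasts over rows."""
        v = np.asarray(values)
        return np.all((v >= self.lower) & (v <= self.upper), axis=-1)

    def log_volume(self) -> float:
        return float(np.sum(np.log(self.width)))

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
        shape = (len(self.names),) if size is None else (size, len(self.names))
        return rng.uniform(self.lower, self.upper, size=shape)

    def subset(self, names: Iterable[str]) -> "PriorSpec":
        names = tuple(names)
        idx = [self.names.index(n) for n in names]
        return PriorSpec(names, self.lower[idx], self.upper[idx])


def default_prior(
    model: ModelSpec, overrides: Mapping[str, tuple[float, float]] | None = None
) -> PriorSpec:
    """Default prior box for a model, with per-parameter overrides.

    Overrides are (lower, upper) on sampling scale and may be keyed either
    by full parameter name (``"beta_CLN3"``) or by class prefix
    (``"beta"``, ``"m0"``, ...).
    """
    names = param_names(model)
    lo = np.empty(len(names))
    hi = np.empty(len(names))
    overrides = dict(overrides or {})
    for i, n in enumerate(names):
        prefix = n.split("_", 1)[0]
        bound = overrides.get(n) or overrides.get(prefix) or _DEFAULT_BOUNDS[_param_class(n)]
        lo[i], hi[i] = bound
    return PriorSpec(names, lo, hi)


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------

def inhibition_factor(conc, K, h):
    """Hill repression factor ``1 / (1 + (conc / K)^h)`` in (0, 1].

    Monotone non-increasing in ``conc``; equals 1 with no inhibitor
    (``conc = 0``) and 1/2 at ``conc = K``.
    """
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("inhibitor concentration must be non-negative")
    if not (np.all(np.asarray(K) > 0) and np.all(np.asarray(h) > 0)):
        raise ValueError("K and h must be positive")
    out = 1.0 / (1.0 + (conc / K) ** h)
    return float(out) if out.ndim == 0 else out


@dataclass
class _CompiledRates:
    """Model structure + linear parameters unpacked into index arrays."""

    beta: np.ndarray       # (G,) uM/s
    alpha: np.ndarray      # (G,) 1/s; 0 where no activator
    act_idx: np.ndarray    # (G,) activator gene index, -1 for none
    deltap: np.ndarray     # (G,) 1/s
    deltam: float
    kappa: float
    tinh_idx: np.ndarray   # (G,) transcription-inhibitor gene index, -1 none
    tinh_K: np.ndarray
    tinh_h: np.ndarray
    dinh_idx: np.ndarray   # (G,) degradation-inhibitor gene index, -1 none
    dinh_K: np.ndarray
    dinh_h: np.ndarray
    m0: np.ndarray
    p0: np.ndarray


def compile_rates(model: ModelSpec, params: ParameterVector | Mapping[str, float]) -> _CompiledRates:
    """Unpack a parameter vector into dense arrays for fast RHS evaluation.

    ``params`` may be a sampling-scale :class:`ParameterVector` or an
    already-linear mapping.
    """
    lin = params.to_linear() if isinstance(params, ParameterVector) else dict(params)
    G = model.n_genes
    gi = {g.name: i for i, g in enumerate(model.genes)}
    beta = np.empty(G)
    alpha = np.zeros(G)
    act_idx = np.full(G, -1, dtype=int)
    deltap = np.empty(G)
    tinh_idx = np.full(G, -1, dtype=int)
    tinh_K = np.ones(G)
    tinh_h = np.ones(G)
    dinh_idx = np.full(G, -1, dtype=int)
    dinh_K = np.ones(G)
    dinh_h = np.ones(G)
    m0 = np.empty(G)
    p0 = np.empty(G)
    try:
        for i, g in enumerate(model.genes):
            beta[i] = lin[f"beta_{g.name}"]
            if g.activator is not None:
                alpha[i] = lin[f"alpha_{g.name}"]
                act_idx[i] = gi[g.activator]
            deltap[i] = lin[f"deltap_{g.name}"]
            m0[i] = lin[f"m0_{g.name}"]
            p0[i] = lin[f"p0_{g.name}"]
            if g.transcription_inhibitor is not None:
                tinh_idx[i] = gi[g.transcription_inhibitor]
                tinh_K[i] = lin[f"K_{g.name}"]
                tinh_h[i] = lin[f"h_{g.name}"]
            if g.degradation_inhibitor is not None:
                dinh_idx[i] = gi[g.degradation_inhibitor]
                dinh_K[i] = lin[f"Kdeg_{g.name}"]
                dinh_h[i] = lin[f"hdeg_{g.name}"]
        deltam = lin["deltam"]
        kappa = lin["kappa"]
    except KeyError as e:
        raise ConfigurationError(f"missing parameter for model: {e}") from None
    return _CompiledRates(
        beta=beta, alpha=alpha, act_idx=act_idx, deltap=deltap,
        deltam=float(deltam), kappa=float(kappa),
        tinh_idx=tinh_idx, tinh_K=tinh_K, tinh_h=tinh_h,
        dinh_idx=dinh_idx, dinh_K=dinh_K, dinh_h=dinh_h, m0=m0, p0=p0,
    )


def rhs(t: float, state: np.ndarray, model: ModelSpec,
        params: ParameterVector | _CompiledRates) -> np.ndarray:
    """Time derivatives (uM/s) of all species at ``state`` (uM).

    State layout follows :attr:`ModelSpec.species`: the first ``G`` entries
    are mRNA concentrations, the last ``G`` proteins.
    """
    c = params if isinstance(params, _CompiledRates) else compile_rates(model, params)
    state = np.asarray(state, dtype=float)
    G = model.n_genes
    if state.shape != (2 * G,):
        raise ValueError(f"state length {state.shape} != species count {2 * G}")
    m = state[:G]
    P = state[G:]

    transcription = c.beta.copy()
    has_act = c.act_idx >= 0
    if has_act.any():
        transcription[has_act] += c.alpha[has_act] * P[c.act_idx[has_act]]
    has_tinh = c.tinh_idx >= 0
    if has_tinh.any():
        x = np.maximum(P[c.tinh_idx[has_tinh]], 0.0)
        transcription[has_tinh] *= 1.0 / (
            1.0 + (x / c.tinh_K[has_tinh]) ** c.tinh_h[has_tinh]
        )
    dm = transcription - c.deltam * m

    deg = c.deltap * P
    has_dinh = c.dinh_idx >= 0
    if has_dinh.any():
        x = np.maximum(P[c.dinh_idx[has_dinh]], 0.0)
        deg[has_dinh] *= 1.0 / (1.0 + (x / c.dinh_K[has_dinh]) ** c.dinh_h[has_dinh])
    dP = c.kappa * m - deg
    return np.concatenate([dm, dP])
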