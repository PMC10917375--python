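"""Generative model for task fMRI effective connectivity.

The neural level is the bilinear state equation

    dx/dt = (A + sum_j u_j(t) B_j) x + C u(t)

over a small set of regions, where ``A`` holds intrinsic (condition
independent) coupling, each ``B_j`` holds the modulation of coupling by
experimental condition ``j``, and ``C`` holds direct driving inputs.
Off-diagonal entries are rates in Hz.  Diagonal entries are unitless
log-scaling parameters of a fixed self-decay: the effective
self-connection of region ``i`` is ``-0.5 * exp(a_ii + sum_j u_j b_j,ii)``
Hz, so it is strictly negative for every admissible parameter value and
equals -0.5 Hz when the log parameter is zero.

Neural activity drives a balloon/Windkessel hemodynamic cascade per
region (vasodilatory signal ``s``, inflow ``f``, blood volume ``v``,
deoxyhemoglobin ``q``) whose output is the BOLD percent signal change.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _integrate

__all__ = [
    "NODE_LABELS",
    "SELF_DECAY_HZ",
    "HemodynamicParameters",
    "DCMParameters",
    "ExperimentDesign",
    "LatentState",
    "RegionTimeSeries",
    "SimulationError",
    "jacobian_at",
    "neural_derivative",
    "hemodynamic_derivative",
    "bold_observation",
    "simulate_bold",
]

#: Canonical node ordering used everywhere in this package.
NODE_LABELS = ("IFG", "Cau", "GP", "Thal")

#: Default self-connection rate at zero log-scaling parameter (Hz).
SELF_DECAY_HZ = -0.5

#: Bound on |neural activity| beyond which a simulation is declared unstable.
STABILITY_BOUND = 1e3


class SimulationError(RuntimeError):
    """Raised when forward integration leaves the stable regime."""


@dataclass
class HemodynamicParameters:
    """Per-region balloon model constants.

    Rates are per second, times in seconds; ``alpha`` (vessel stiffness),
    ``E0`` (resting oxygen extraction) and ``V0`` (resting venous volume
    fraction) are unitless.  Defaults are the canonical published values
    for 3T BOLD with the revised output coefficients
    ``k1 = 4.3 nu0 E0 TE``, ``k2 = eps r0 E0 TE``, ``k3 = 1 - eps``.
    """

    kappa: np.ndarray  # signal decay rate (1/s)
    gamma: np.ndarray  # autoregulation rate (1/s)
    tau: np.ndarray    # mean transit time (s)
    alpha: np.ndarray  # stiffness exponent
    E0: np.ndarray     # resting oxygen extraction fraction
    V0: np.ndarray     # resting venous volume fraction
    TE: float = 0.03   # echo time (s)
    nu0: float = 40.3  # frequency offset of fully deoxygenated blood (1/s)
    r0: float = 25.0   # intravascular relaxation slope (1/s)
    epsilon: float = 1.0  # intra/extravascular signal ratio

    @classmethod
    def default(cls, n_nodes: int = 4) -> "HemodynamicParameters":
        ones = np.ones(n_nodes)
        return cls(
            kappa=0.64 * ones,
            gamma=0.32 * ones,
            tau=2.0 * ones,
            alpha=0.32 * ones,
            E0=0.4 * ones,
            V0=0.04 * ones,
        )

    def validate(self) -> None:
        for name in ("kappa", "gamma", "tau", "alpha", "E0", "V0"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"hemodynamic parameter {name} must be 1-D")
        if not np.all((self.alpha > 0) & (self.alpha < 1)):
            raise ValueError("alpha must lie in (0, 1)")
        if not np.all((self.E0 > 0) & (self.E0 < 1)):
            raise ValueError("E0 must lie in (0, 1)")
        if not np.all(self.tau > 0):
            raise ValueError("transit time tau must be positive")

    def output_coefficients(self) -> tuple[float, float, float]:
        """Revised BOLD output coefficients (k1, k2, k3) — k1/k2 per node."""
        k1 = 4.3 * self.nu0 * np.asarray(self.E0) * self.TE
        k2 = self.epsilon * self.r0 * np.asarray(self.E0) * self.TE
        k3 = 1.0 - self.epsilon
        return k1, k2, k3


@dataclass
class DCMParameters:
    """One subject's generative model.

    ``A`` and each ``B`` are node x node with the [target, source]
    convention; ``C`` is node x driving-input.  ``noise_log_precisions``
    give per-node observation noise variance ``exp(-lp)``.
    """

    A: np.ndarray
    B: np.ndarray  # (n_modulatory, n, n)
    C: np.ndarray  # (n, n_driving)
    hemo: HemodynamicParameters = None
    noise_log_precisions: np.ndarray = None
    node_labels: tuple = NODE_LABELS

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ValueError("A must be square")
        if self.B.ndim != 3 or self.B.shape[1:] != (n, n):
            raise ValueError("B must be a stack of square matrices matching A")
        if self.C.ndim != 2 or self.C.shape[0] != n:
            raise ValueError("C must have one row per node")
        if self.hemo is None:
            self.hemo = HemodynamicParameters.default(n)
        self.hemo.validate()
        if self.noise_log_precisions is None:
            self.noise_log_precisions = np.full(n, 4.0)
        self.noise_log_precisions = np.asarray(self.noise_log_precisions, float)

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    @classmethod
    def zeros(cls, n_nodes: int = 4, n_modulatory: int = 2,
              n_driving: int = 2, node_labels: tuple = NODE_LABELS) -> "DCMParameters":
        return cls(
            A=np.zeros((n_nodes, n_nodes)),
            B=np.zeros((n_modulatory, n_nodes, n_nodes)),
            C=np.zeros((n_nodes, n_driving)),
            node_labels=tuple(node_labels[:n_nodes]),
        )

    # -- JSON round trip -------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        labels = list(self.node_labels)
        payload = {
            "node_labels": labels,
            "A": {"rows": labels, "cols": labels, "values": self.A.tolist()},
            "B": [{"rows": labels, "cols": labels, "values": b.tolist()}
                  for b in self.B],
            "C": {"rows": labels, "values": self.C.tolist()},
            "hemo": {
                k: np.asarray(getattr(self.hemo, k)).tolist()
                for k in ("kappa", "gamma", "tau", "alpha", "E0", "V0")
            } | {"TE": self.hemo.TE, "nu0": self.hemo.nu0,
                 "r0": self.hemo.r0, "epsilon": self.hemo.epsilon},
            "noise_log_precisions": self.noise_log_precisions.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "DCMParameters":
        d = json.loads(Path(path).read_text())
        hemo = HemodynamicParameters(
            kappa=np.array(d["hemo"]["kappa"]),
            gamma=np.array(d["hemo"]["gamma"]),
            tau=np.array(d["hemo"]["tau"]),
            alpha=np.array(d["hemo"]["alpha"]),
            E0=np.array(d["hemo"]["E0"]),
            V0=np.array(d["hemo"]["V0"]),
            TE=d["hemo"]["TE"], nu0=d["hemo"]["nu0"],
            r0=d["hemo"]["r0"], epsilon=d["hemo"]["epsilon"],
        )
        return cls(
            A=np.array(d["A"]["values"]),
            B=np.array([b["values"] for b in d["B"]]),
            C=np.array(d["C"]["values"]),
            hemo=hemo,
            noise_log_precisions=np.array(d["noise_log_precisions"]),
            node_labels=tuple(d["node_labels"]),
        )


@dataclass
class ExperimentDesign:
    """Condition input functions and sampling grid for one session.

    ``inputs`` holds raw 0/1 condition boxcars at microtime resolution,
    shaped (n_runs, n_micro_per_run, n_inputs).  With ``mean_center``
    each input's temporal mean (over the whole session) is subtracted
    before it enters the model, so the A matrix represents mean
    effective connectivity across conditions.
    """

    inputs: np.ndarray
    input_names: tuple
    TR: float
    n_volumes: int          # per run
    microtime_dt: float
    mean_center: bool = True
    modulatory_input_ids: tuple = None
    driving_input_ids: tuple = None

    def __post_init__(self):
        self.inputs = np.asarray(self.inputs, dtype=float)
        if self.inputs.ndim != 3:
            raise ValueError("inputs must be (n_runs, n_micro, n_inputs)")
        micro_per_tr = self.TR / self.microtime_dt
        if abs(micro_per_tr - round(micro_per_tr)) > 1e-9:
            raise ValueError("microtime_dt must divide TR")
        if self.inputs.shape[1] != self.n_volumes * round(micro_per_tr):
            raise ValueError("input length inconsistent with n_volumes * TR")
        if self.modulatory_input_ids is None:
            self.modulatory_input_ids = tuple(range(self.inputs.shape[2]))
        if self.driving_input_ids is None:
            self.driving_input_ids = tuple(range(self.inputs.shape[2]))

    @property
    def n_runs(self) -> int:
        return self.inputs.shape[0]

    @property
    def micro_per_tr(self) -> int:
        return round(self.TR / self.microtime_dt)

    @property
    def duration(self) -> float:
        return self.n_runs * self.n_volumes * self.TR

    def centered_inputs(self) -> np.ndarray:
        """Inputs as they enter the model (mean-centered if requested)."""
        u = self.inputs
        if self.mean_center:
            u = u - u.mean(axis=(0, 1), keepdims=True)
        return u


@dataclass
class LatentState:
    """Neural and hemodynamic state of all regions at one instant.

    At rest (x = 0, zero input) the hemodynamic state (s, f, v, q) =
    (0, 1, 1, 1) is a fixed point of the cascade.
    """

    x: np.ndarray
    s: np.ndarray
    f: np.ndarray
    v: np.ndarray
    q: np.ndarray

    @classmethod
    def rest(cls, n_nodes: int = 4) -> "LatentState":
        z = np.zeros(n_nodes)
        o = np.ones(n_nodes)
        return cls(x=z.copy(), s=z.copy(), f=o.copy(), v=o.copy(), q=o.copy())


@dataclass
class RegionTimeSeries:
    """BOLD signal per node, sampled at TR, possibly over several runs."""

    values: np.ndarray          # (n_volumes_total, n_nodes)
    TR: float
    run_starts: tuple           # volume index at which each run begins
    node_labels: tuple = NODE_LABELS
    metadata: dict = field(default_factory=dict)
    confounds: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")
        if tuple(self.run_starts)[0] != 0:
            raise ValueError("first run must start at volume 0")
        self.run_starts = tuple(self.run_starts)

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    def run_slices(self) -> list[slice]:
        bounds = list(self.run_starts) + [self.n_volumes]
        return [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:])]

    # -- TSV + sidecar round trip ---------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        path = Path(path)
        t = np.arange(self.n_volumes) * self.TR
        df = pd.DataFrame({"time_s": t})
        for j, lab in enumerate(self.node_labels):
            df[lab] = self.values[:, j]
        df.to_csv(path, sep="\t", index=False)
        sidecar = {
            "TR": self.TR,
            "run_starts": list(self.run_starts),
            "node_labels": list(self.node_labels),
            "units": self.metadata.get("units", "percent signal change"),
            "metadata": {k: v for k, v in self.metadata.items() if k != "units"},
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RegionTimeSeries":
        import pandas as pd

        path = Path(path)
        side = json.loads(path.with_suffix(".json").read_text())
        df = pd.read_csv(path, sep="\t")
        labels = tuple(side["node_labels"])
        return cls(
            values=df[list(labels)].to_numpy(),
            TR=side["TR"],
            run_starts=tuple(side["run_starts"]),
            node_labels=labels,
            metadata={"units": side.get("units")} | side.get("metadata", {}),
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def jacobian_at(params: DCMParameters, u: Sequence[float]) -> np.ndarray:
    """Effective coupling matrix J(u) in Hz at modulatory input values ``u``.

    Off-diagonal: ``A[i,k] + sum_j u_j B_j[i,k]``.  Diagonal:
    ``-0.5 * exp(A[i,i] + sum_j u_j B_j[i,i])`` — always negative.
    """
    u = np.asarray(u, dtype=float)
    if u.shape != (params.B.shape[0],):
        raise ValueError(
            f"expected {params.B.shape[0]} modulatory input values, got {u.shape}"
        )
    M = params.A + np.tensordot(u, params.B, axes=1)
    J = M.copy()
    d = np.diag_indices(params.n_nodes)
    J[d] = SELF_DECAY_HZ * np.exp(M[d])
    return J


def neural_derivative(params: DCMParameters, u: Sequence[float],
                      x: np.ndarray,
                      u_driving: Sequence[float] | None = None) -> np.ndarray:
    """dx/dt = J(u) x + C u_driving (1/s).

    If ``u_driving`` is omitted the modulatory input values are reused
    (the usual case: the same condition functions modulate and drive).
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("neural state must be finite")
    if u_driving is None:
        u_driving = u
    u_driving = np.asarray(u_driving, dtype=float)
    if u_driving.shape != (params.C.shape[1],):
        raise ValueError("driving input dimension mismatch")
    return jacobian_at(params, u) @ x + params.C @ u_driving


def hemodynamic_derivative(hemo: HemodynamicParameters, x: np.ndarray,
                           state: LatentState) -> LatentState:
    """Balloon model time derivatives for all regions.

    ds/dt = x - kappa s - gamma (f - 1);  df/dt = s;
    tau dv/dt = f - v**(1/alpha);
    tau dq/dt = f (1 - (1-E0)**(1/f))/E0 - v**(1/alpha) q/v.
    """
    s, f, v, q = state.s, state.f, state.v, state.q
    if np.any(v <= 0) or np.any(q <= 0) or not np.all(np.isfinite(f)):
        raise SimulationError("hemodynamic state left the physical domain")
    fv = v ** (1.0 / hemo.alpha)
    ds = x - hemo.kappa * s - hemo.gamma * (f - 1.0)
    df = s
    dv = (f - fv) / hemo.tau
    dq = (f * (1.0 - (1.0 - hemo.E0) ** (1.0 / f)) / hemo.E0
          - fv * q / v) / hemo.tau
    return LatentState(x=np.zeros_like(s), s=ds, f=df, v=dv, q=dq)


def bold_observation(hemo: HemodynamicParameters, state: LatentState) -> np.ndarray:
    """BOLD percent signal change per region; exactly zero at rest."""
    k1, k2, k3 = hemo.output_coefficients()
    v, q = state.v, state.q
    return 100.0 * hemo.V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v)
                              + k3 * (1.0 - v))


def simulate_bold(params: DCMParameters, design: ExperimentDesign,
                  noise_seed: int | None = None,
                  return_neural: bool = False):
    """Integrate the generative model and sample BOLD at each TR.

    Runs are integrated independently from rest (no carry-over of
    dynamics between runs).  The neural substep uses the exact local
    matrix exponential of J(u) over each microtime bin (inputs are
    piecewise constant); the hemodynamic states advance by RK4.
    Observation noise with per-node variance ``exp(-noise_log_precision)``
    is appended only when a seed is given, so the noiseless call is a
    pure function of (params, design).
    """
    hemo = {k: v[None] for k, v in _hemo_arrays(params.hemo).items()}
    y, x = _integrate.integrate_batch(
        params.A[None], params.B[None], params.C[None], hemo, design,
    )
    y = y[0]
    if noise_seed is not None:
        rng = np.random.default_rng(noise_seed)
        std = np.exp(-0.5 * params.noise_log_precisions)
        y = y + rng.normal(size=y.shape) * std
    ts = RegionTimeSeries(
        values=y,
        TR=design.TR,
        run_starts=tuple(r * design.n_volumes for r in range(design.n_runs)),
        node_labels=params.node_labels,
        metadata={
            "units": "percent signal change",
            "noise_seed": noise_seed,
            "microtime_dt": design.microtime_dt,
        },
    )
    if return_neural:
        return ts, x[0]
    return ts


def _hemo_arrays(hemo: HemodynamicParameters) -> dict:
    k1, k2, k3 = hemo.output_coefficients()
    return {
        "kappa": np.asarray(hemo.kappa, float),
        "gamma": np.asarray(hemo.gamma, float),
        "tau": np.asarray(hemo.tau, float),
        "alpha": np.asarray(hemo.alpha, float),
        "E0": np.asarray(hemo.E0, float),
        "V0": np.asarray(hemo.V0, float),
        "k1": np.asarray(k1, float),
        "k2": np.asarray(k2, float),
        "k3": np.full_like(np.asarray(hemo.kappa, float), k3),
    }
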