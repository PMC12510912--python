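"""Steady-state glymphatic forward models.

Two linear elliptic systems typical of brain solute-transport modeling:

* **Model A** — two-compartment tracer transport: diffusion of an MRI
  tracer in the extracellular space (ECS, concentration ``c_e``) and the
  perivascular spaces (PVS, ``c_p``) with membrane exchange between the two,
  weak clearance from PVS to blood, and Robin boundary conditions carrying
  an idealized CSF tracer concentration on the pial and ventricular
  surfaces.  Discretized with quadratic (P2) Lagrange elements.

* **Model B** — seven-compartment steady multiple-network poroelasticity
  (MPET, elastic terms dropped): Darcy-type pressure fields for arterial /
  capillary / venous blood (``p_a, p_c, p_v``), their perivascular spaces
  (``p_pa, p_pc, p_pv``) and the extracellular space (``p_e``), coupled by
  pairwise pressure-driven exchange ``omega_ij (p_j - p_i)``.  Arterial
  inflow enters as a Neumann flux on the pial surface, choroid-plexus
  production as a capillary efflux on the ventricular surface, and three
  Robin conditions anchor the venous and perivascular pressures to dural
  sinus / CSF reference pressures.  Discretized with linear (P1) elements.

Internal unit regime: mm - s - Pa.  Literature values quoted in SI are
converted on construction (1 m^2 = 1e6 mm^2, 1 mmHg = 133.322 Pa,
1 ml/min = 1000/60 mm^3/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .fem import (
    AssembledSystem,
    FESpace,
    Field,
    Mesh,
    PIAL,
    VENTRICLE,
    assemble_operator,
    build_space,
    solve_full,
)

MMHG = 133.322           # Pa per mmHg
ML_PER_MIN = 1000.0 / 60.0   # mm^3/s per ml/min

MODEL_A_FIELDS = ("c_e", "c_p")
MODEL_B_FIELDS = ("p_a", "p_c", "p_v", "p_pa", "p_pc", "p_pv", "p_e")
COMPARTMENTS = ("a", "c", "v", "pa", "pc", "pv", "e")


# ---------------------------------------------------------------------------
# CSF boundary concentration profile (model A)
# ---------------------------------------------------------------------------

@dataclass
class BoundaryProfile:
    """Idealized tracer concentration in the CSF after intrathecal injection.

    c(t) = (a / phi) * (exp(-t / tau2) - exp(-t / tau1)),  tau2 > tau1 > 0:
    zero at injection, rising on the slow scale tau2 and cleared on the fast
    scale tau1, with amplitude ``amplitude`` [mm^2/s as tabulated] divided by
    the CSF volume fraction ``phi_vf``.
    """

    amplitude: float
    phi_vf: float = 0.2
    tau1: float = 4.43e4
    tau2: float = 8.5e4

    def __post_init__(self) -> None:
        if not (0 < self.phi_vf <= 1):
            raise ValueError("phi_vf must be in (0, 1]")
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("time constants must be positive")


def csf_concentration(profile: BoundaryProfile, t) -> np.ndarray | float:
    """Evaluate the CSF concentration profile at time(s) t [s]."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = (profile.amplitude / profile.phi_vf) * (
        np.exp(-t / profile.tau2) - np.exp(-t / profile.tau1)
    )
    return float(out) if out.ndim == 0 else out


def peak_time(profile: BoundaryProfile) -> float:
    """Closed-form argmax of the profile [s].

    Setting dc/dt = 0 gives t* = ln(tau2 / tau1) / (1/tau1 - 1/tau2).
    """
    t1, t2 = profile.tau1, profile.tau2
    if not t2 > t1 > 0:
        raise ValueError("peak time requires tau2 > tau1 > 0")
    return float(np.log(t2 / t1) / (1.0 / t1 - 1.0 / t2))


# ---------------------------------------------------------------------------
# Model A parameters
# ---------------------------------------------------------------------------

@dataclass
class ModelAParams:
    """Two-compartment tracer model parameters (mm - s units).

    Defaults are the tabulated low-clearance variant: volume fractions
    ``n_e`` (ECS) and ``n_p`` (PVS), free diffusion coefficients ``D_e`` and
    ``D_p`` [mm^2/s], ECS<->PVS transfer ``pi_ep`` [1/s], PVS->blood
    clearance ``pi_pb`` [1/s], and membrane conductivities ``k_e``, ``k_p``
    [mm/s] shared by the pial and ventricular surfaces.  The CSF boundary
    amplitudes are surface-specific (``a_pial``, ``a_ventricle``); the
    boundary concentration is evaluated at ``t_eval`` [s], by default the
    profile's peak (~16.7 h post injection).
    """

    n_e: float = 0.2
    n_p: float = 0.02
    D_e: float = 1.3e-4
    D_p: float = 3.9e-4
    pi_ep: float = 2.9e-2
    pi_pb: float = 2.0e-8
    k_e: float = 1.0e-5
    k_p: float = 3.7e-4
    a_pial: float = 0.52
    a_ventricle: float = 0.2
    phi_vf: float = 0.2
    tau1: float = 4.43e4
    tau2: float = 8.5e4
    t_eval: float = 16.7 * 3600.0

    def __post_init__(self) -> None:
        positives = dict(n_e=self.n_e, n_p=self.n_p, D_e=self.D_e, D_p=self.D_p,
                         k_e=self.k_e, k_p=self.k_p, tau1=self.tau1, tau2=self.tau2,
                         t_eval=self.t_eval)
        for name, v in positives.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pi_ep < 0 or self.pi_pb < 0:
            raise ValueError("transfer coefficients must be nonnegative")
        if not (0 < self.phi_vf <= 1):
            raise ValueError("phi_vf must be in (0, 1]")

    def profile(self, surface: str) -> BoundaryProfile:
        amp = {"pial": self.a_pial, "ventricle": self.a_ventricle}[surface]
        return BoundaryProfile(amp, self.phi_vf, self.tau1, self.tau2)

    def boundary_concentration(self, surface: str) -> float:
        return csf_concentration(self.profile(surface), self.t_eval)


def assemble_model_a(space: FESpace, params: ModelAParams,
                     deformation_jacobian=None) -> AssembledSystem:
    """Assemble the two-compartment system on a 2-field P2 (or P1) space.

    Field block 0 is ``c_e``, block 1 is ``c_p``.  The exchange term
    pi_ep (c_p - c_e) is dissipative; clearance pi_pb acts on ``c_p`` only.
    Robin conditions -n_a D_a grad c_a . n = k_a (c_a - c_CSF) are applied on
    both markers with surface-specific CSF concentrations.
    """
    if space.n_fields != 2:
        raise ValueError("model A needs a 2-field space (c_e, c_p)")
    g_pial = params.boundary_concentration("pial")
    g_vent = params.boundary_concentration("ventricle")
    return assemble_operator(
        space,
        diffusion=[params.n_e * params.D_e, params.n_p * params.D_p],
        exchange=np.array([[0.0, params.pi_ep], [params.pi_ep, 0.0]]),
        reaction=[0.0, params.pi_pb],
        robin=[
            (0, PIAL, params.k_e, g_pial),
            (0, VENTRICLE, params.k_e, g_vent),
            (1, PIAL, params.k_p, g_pial),
            (1, VENTRICLE, params.k_p, g_vent),
        ],
        deformation_jacobian=deformation_jacobian,
    )


# ---------------------------------------------------------------------------
# Model B parameters
# ---------------------------------------------------------------------------

# Tabulated base-variant values: permeabilities kappa_i [m^2] and symmetric
# transfer coefficients omega_ij [1/(Pa s)] on the compartment graph
# {a-c, c-v, c-pc, pa-e, pv-e, pa-pc, pc-pv, pc-e}.
KAPPA_M2 = {
    "a": 3.63e-14, "c": 1.44e-15, "v": 1.13e-12,
    "e": 2e-17, "pa": 3e-17, "pc": 1.44e-15, "pv": 1.95e-14,
}
OMEGA_PAIRS = {
    ("a", "c"): 1.45e-6,
    ("c", "v"): 8.75e-6,
    ("c", "pc"): 8.48e-10,
    ("pa", "e"): 1.86e-7,
    ("pv", "e"): 1.65e-7,
    ("pa", "pc"): 1e-6,
    ("pc", "pv"): 1e-6,
    ("pc", "e"): 1e-10,
}
# Fluid viscosities [Pa s]: NOT tabulated by the reference parameter set we
# mirror (which quotes effective conductivities downstream); these are
# conventional values for blood and CSF and are config-exposed.
MU_DEFAULT = {"a": 2.67e-3, "c": 2.67e-3, "v": 2.67e-3,
              "pa": 7.0e-4, "pc": 7.0e-4, "pv": 7.0e-4, "e": 7.0e-4}


@dataclass
class ModelBParams:
    """Steady 7-network MPET parameters (mm - s - Pa internally).

    ``kappa_m2`` [m^2] and ``mu`` [Pa s] give effective conductivities
    K_i = kappa_i / mu_i, converted to mm^2/(Pa s); ``omega`` maps unordered
    compartment pairs to exchange coefficients [1/(Pa s)].  ``B_in`` is the
    total arterial inflow [mm^3/s in 3D; mm^2/s for the 2D slice analogue],
    distributed uniformly over the measured pial boundary;
    ``Q_prod`` the choroid-plexus production rate leaving the capillaries
    across the ventricular surface.  ``p_DS`` and ``p_CSF`` are dural-sinus
    and CSF reference pressures [Pa]; ``beta1..beta3`` boundary conductances.

    ``B_in``, ``p_CSF`` and ``mu`` defaults are modeling choices, not
    tabulated values (see docs/methods.md); override them in config for any
    quantitative use.
    """

    kappa_m2: dict = dataclass_field(default_factory=lambda: dict(KAPPA_M2))
    mu: dict = dataclass_field(default_factory=lambda: dict(MU_DEFAULT))
    omega: dict = dataclass_field(default_factory=lambda: dict(OMEGA_PAIRS))
    B_in: float = 20.0                     # mm^2/s on the 2D slice; NOT-FROM-TABLES
    Q_prod: float = 0.33 * ML_PER_MIN      # mm^3/s (0.33 ml/min)
    p_DS: float = 8.4 * MMHG               # Pa
    p_CSF: float = 10.0 * MMHG             # Pa; NOT-FROM-TABLES
    beta1: float = 1e-3
    beta2: float = 1e-3
    beta3: float = 1e-7

    def __post_init__(self) -> None:
        for c in COMPARTMENTS:
            if self.kappa_m2.get(c, 0) <= 0 or self.mu.get(c, 0) <= 0:
                raise ValueError(f"kappa and mu must be positive for compartment {c!r}")
        for pair, w in self.omega.items():
            if w < 0:
                raise ValueError(f"omega{pair} must be nonnegative")
        if not self._graph_connected():
            raise ValueError("compartment exchange graph is not connected")

    def _graph_connected(self) -> bool:
        adj = {c: set() for c in COMPARTMENTS}
        for (i, j), w in self.omega.items():
            if w > 0:
                adj[i].add(j)
                adj[j].add(i)
        seen = {COMPARTMENTS[0]}
        stack = [COMPARTMENTS[0]]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == len(COMPARTMENTS)

    def conductivity(self, c: str) -> float:
        """Effective conductivity K = kappa / mu in mm^2/(Pa s)."""
        return self.kappa_m2[c] * 1e6 / self.mu[c]

    def exchange_matrix(self) -> np.ndarray:
        n = len(COMPARTMENTS)
        idx = {c: i for i, c in enumerate(COMPARTMENTS)}
        W = np.zeros((n, n))
        for (i, j), w in self.omega.items():
            W[idx[i], idx[j]] = W[idx[j], idx[i]] = w
        return W


def assemble_model_b(space: FESpace, params: ModelBParams, mesh: Mesh | None = None,
                     deformation_jacobian=None) -> AssembledSystem:
    """Assemble the 7-field MPET system (field order = COMPARTMENTS).

    Exchange follows the dissipative convention -div(K_i grad p_i) =
    sum_j omega_ij (p_j - p_i) (flow down pressure gradients).  Boundary
    data: arterial Neumann influx Q_in = B_in / |pial boundary| on the pial
    surface; capillary Neumann efflux -Q_prod / |ventricular boundary| on
    the ventricle; Robin anchors beta1 ((p_DS + p_CSF)/2 - p_v),
    beta2 (p_CSF - p_pa) and beta3 ((p_DS + p_CSF)/2 - p_pv) on the pial
    surface; homogeneous Neumann elsewhere.  Totals are divided by the
    boundary measure of the assembly mesh, so the prescribed in/outflows are
    geometry-independent.
    """
    if space.n_fields != len(COMPARTMENTS):
        raise ValueError("model B needs a 7-field space")
    mesh = space.mesh if mesh is None else mesh
    len_pial = mesh.boundary_length(PIAL)
    len_vent = mesh.boundary_length(VENTRICLE)
    q_in = params.B_in / len_pial
    q_prod = params.Q_prod / len_vent
    p_mid = 0.5 * (params.p_DS + params.p_CSF)
    i = {c: k for k, c in enumerate(COMPARTMENTS)}
    return assemble_operator(
        space,
        diffusion=[params.conductivity(c) for c in COMPARTMENTS],
        exchange=params.exchange_matrix(),
        robin=[
            (i["v"], PIAL, params.beta1, p_mid),
            (i["pa"], PIAL, params.beta2, params.p_CSF),
            (i["pv"], PIAL, params.beta3, p_mid),
        ],
        neumann=[
            (i["a"], PIAL, q_in),
            (i["c"], VENTRICLE, -q_prod),
        ],
        deformation_jacobian=deformation_jacobian,
    )


# ---------------------------------------------------------------------------
# Unified front end
# ---------------------------------------------------------------------------

MODEL_ORDER = {"A": 2, "B": 1}


def model_space(mesh: Mesh, which: str) -> FESpace:
    """The discretization used for each model: P2x2 for A, P1x7 for B."""
    which = which.upper()
    if which == "A":
        return build_space(mesh, order=2, n_fields=2)
    if which == "B":
        return build_space(mesh, order=1, n_fields=len(COMPARTMENTS))
    raise ValueError("which must be 'A' or 'B'")


def assemble_model(space: FESpace, which: str, params=None,
                   deformation_jacobian=None) -> AssembledSystem:
    which = which.upper()
    if which == "A":
        params = ModelAParams() if params is None else params
        return assemble_model_a(space, params,
                                deformation_jacobian=deformation_jacobian)
    params = ModelBParams() if params is None else params
    return assemble_model_b(space, params,
                            deformation_jacobian=deformation_jacobian)


def solve_model(mesh: Mesh, which: str, params=None, method: str = "direct") -> Field:
    """High-fidelity solve of model A or B on a mesh; returns a named Field."""
    which = which.upper()
    space = model_space(mesh, which)
    system = assemble_model(space, which, params)
    x = solve_full(system, method=method)
    names = MODEL_A_FIELDS if which == "A" else MODEL_B_FIELDS
    return Field(space, x, field_names=names)


def total_tracer_mass(field: Field, params: ModelAParams) -> float:
    """Integral of n_e c_e + n_p c_p over the domain (model A diagnostics)."""
    from .fem import mass_matrix

    M = mass_matrix(field.space)
    ones = np.ones(field.space.D)
    return float(params.n_e * (ones @ (M @ field.by_name("c_e")))
                 + params.n_p * (ones @ (M @ field.by_name("c_p"))))


def model_b_boundary_fluxes(field: Field, params: ModelBParams) -> dict:
    """Net boundary in/outflows of the MPET solution, by term.

    Positive = into the domain.  At steady state with conservative exchange,
    the terms must sum to zero: arterial influx B_in, capillary efflux
    -Q_prod, and the three Robin fluxes beta <g - p> on the pial surface.
    ``imbalance`` is their sum; ``max_term`` the largest magnitude, for a
    relative conservation check.
    """
    from .fem import boundary_integral

    mesh = field.space.mesh
    len_pial = mesh.boundary_length(PIAL)
    p_mid = 0.5 * (params.p_DS + params.p_CSF)
    i = {c: k for k, c in enumerate(COMPARTMENTS)}
    fluxes = {
        "arterial_influx": params.B_in,
        "capillary_efflux": -params.Q_prod,
        "venous_robin": params.beta1 * (
            p_mid * len_pial - boundary_integral(field, i["v"], PIAL)),
        "pa_robin": params.beta2 * (
            params.p_CSF * len_pial - boundary_integral(field, i["pa"], PIAL)),
        "pv_robin": params.beta3 * (
            p_mid * len_pial - boundary_integral(field, i["pv"], PIAL)),
    }
    fluxes["imbalance"] = sum(fluxes.values())
    fluxes["max_term"] = max(abs(v) for k, v in fluxes.items() if k != "imbalance")
    return fluxes


def boundary_flux(field: Field, system: AssembledSystem) -> float:
    """Global residual functional sum(F - A u) — net imbalance diagnostic.

    For the assembled symmetric systems, testing with the all-ones vector
    measures global conservation: exchange terms cancel pairwise (omega
    symmetry), so the result is the net boundary in/outflow imbalance.
    """
    ones = np.ones_like(field.coeffs)
    return float(ones @ (system.F - system.A @ field.coeffs))
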