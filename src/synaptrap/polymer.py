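"""Worm-like-chain polymer elasticity for hybrid ssDNA/dsDNA tethers.

The tether in these experiments is a serial assembly of

* a double-stranded DNA handle pair, modelled with the extensible
  (enthalpic) worm-like chain,
* a single-stranded DNA segment, modelled with the interpolated
  Marko-Siggia worm-like chain, and
* folded elements (DNA hairpins, an assembled protein-DNA synaptic
  complex) that contribute a force-independent rigid end-to-end offset.

Both chain models share the same entropic backbone

    F = (kBT / p) * [ 1 / (4 (1 - l)^2) - 1/4 + l ]

where ``l`` is the fractional extension: ``x / L`` for ssDNA, and
``x / L - F / K`` for dsDNA with stretch modulus ``K``.  That relation is
a cubic in ``1 - l`` at fixed force, so the inversion extension(force) is
available in closed form (Cardano), optionally polished by one or two
Newton steps; force(extension) for the extensible chain is an implicit
relation solved numerically.

Units throughout: force in pN, length in nm, energy in pN nm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "ThermalContext",
    "DsParams",
    "SsParams",
    "ConstructState",
    "SegmentFit",
    "ms_wlc_force",
    "ss_wlc_extension",
    "ext_wlc_force",
    "ext_wlc_extension",
    "hybrid_extension",
    "hybrid_force",
    "hybrid_compliance",
    "expected_contour_change",
    "fit_segment_contour",
    "tether_states",
    "ss_contour_from_nt",
    "ds_contour_from_bp",
    "hairpin_release",
]

#: canonical helix rises used for contour-length arithmetic
SS_RISE_NM_PER_NT = 0.68
DS_RISE_NM_PER_BP = 0.34


@dataclass(frozen=True)
class ThermalContext:
    """Thermal energy scale.  Default 4.11 pN nm corresponds to ~298 K."""

    kBT: float = 4.11

    def __post_init__(self) -> None:
        if not self.kBT > 0:
            raise ValueError(f"kBT must be positive, got {self.kBT}")


@dataclass(frozen=True)
class DsParams:
    """Extensible-WLC parameters of a dsDNA segment."""

    contour_length: float
    persistence_length: float = 45.0
    stretch_modulus: float = 1200.0

    def __post_init__(self) -> None:
        for name in ("contour_length", "persistence_length", "stretch_modulus"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.persistence_length >= self.contour_length:
            warnings.warn(
                "persistence length >= contour length: not a realistic tether",
                stacklevel=2,
            )


@dataclass(frozen=True)
class SsParams:
    """Marko-Siggia WLC parameters of an ssDNA segment.

    A zero contour length denotes an absent segment (e.g. the spacer
    sequestered inside an assembled synaptic complex).
    """

    contour_length: float
    persistence_length: float = 2.0

    def __post_init__(self) -> None:
        if self.contour_length < 0:
            raise ValueError("ssDNA contour_length must be >= 0")
        if not self.persistence_length > 0:
            raise ValueError("persistence_length must be positive")


@dataclass(frozen=True)
class ConstructState:
    """Mechanical description of the tether in one folding/binding state.

    ``rigid_offsets`` lists folded elements as (label, end-to-end nm)
    pairs: a folded hairpin contributes 2 nm, an assembled synaptic
    complex 10.5 nm.  Total extension at any force is the dsDNA extension
    plus the ssDNA extension plus the summed offsets.
    """

    ds: DsParams
    ss: SsParams
    rigid_offsets: tuple[tuple[str, float], ...] = ()
    ss_rise_per_nt: float = SS_RISE_NM_PER_NT
    ds_rise_per_bp: float = DS_RISE_NM_PER_BP
    label: str = ""

    def __post_init__(self) -> None:
        for name, off in self.rigid_offsets:
            if off < 0:
                raise ValueError(f"rigid offset {name!r} must be >= 0")

    @property
    def offset_total(self) -> float:
        return float(sum(off for _, off in self.rigid_offsets))

    @property
    def contour_coordinate(self) -> float:
        """ssDNA contour plus rigid offsets: the coordinate whose change
        between states is the contour-length fingerprint."""
        return self.ss.contour_length + self.offset_total


def ss_contour_from_nt(nt: float, rise: float = SS_RISE_NM_PER_NT) -> float:
    """Contour length in nm of ``nt`` nucleotides of ssDNA."""
    return nt * rise


def ds_contour_from_bp(bp: float, rise: float = DS_RISE_NM_PER_BP) -> float:
    """Contour length in nm of ``bp`` base pairs of dsDNA."""
    return bp * rise


def hairpin_release(nt: float, folded_offset: float = 2.0,
                    rise: float = SS_RISE_NM_PER_NT) -> float:
    """Contour-length gain from unfolding a hairpin of ``nt`` nucleotides.

    The folded hairpin occupied ``folded_offset`` nm end-to-end; unfolded
    it contributes ``nt * rise`` nm of ssDNA contour.
    """
    return nt * rise - folded_offset


# ---------------------------------------------------------------------------
# Marko-Siggia backbone and its Cardano inversion
# ---------------------------------------------------------------------------

def _ms_reduced_force(l: np.ndarray) -> np.ndarray:
    """Dimensionless Marko-Siggia force f = F p / kBT at fractional extension l."""
    return 1.0 / (4.0 * (1.0 - l) ** 2) - 0.25 + l


def _ms_fractional_extension(f: np.ndarray, newton_steps: int = 2) -> np.ndarray:
    """Invert the Marko-Siggia relation: fractional extension l(f), f >= 0.

    Substituting u = 1 - l turns f = 1/(4 u^2) - 1/4 + (1 - u) into the
    cubic 4 u^3 + (4 f - 3) u^2 - 1 = 0, whose unique root in (0, 1] is
    taken in closed form (Cardano / trigonometric branch) and polished by
    ``newton_steps`` Newton iterations.
    """
    f = np.asarray(f, dtype=float)
    scalar = f.ndim == 0
    f = np.atleast_1d(f)
    if np.any(f < 0):
        raise ValueError("reduced force must be >= 0")

    a = (4.0 * f - 3.0) / 4.0          # cubic: u^3 + a u^2 - 1/4 = 0
    p = -a * a / 3.0
    q = 2.0 * a**3 / 27.0 - 0.25
    disc = q * q / 4.0 + p**3 / 27.0

    u = np.empty_like(f)
    pos = disc >= 0
    if np.any(pos):
        s = np.sqrt(disc[pos])
        u[pos] = (np.cbrt(-q[pos] / 2.0 + s)
                  + np.cbrt(-q[pos] / 2.0 - s)
                  - a[pos] / 3.0)
    if np.any(~pos):
        pn, qn, an = p[~pos], q[~pos], a[~pos]
        m = 2.0 * np.sqrt(-pn / 3.0)
        theta = np.arccos(np.clip(3.0 * qn / (pn * m), -1.0, 1.0))
        # for f > 3/4 the cubic has exactly one root in (0, 1]
        best = np.full_like(pn, np.nan)
        for k in range(3):
            cand = m * np.cos((theta - 2.0 * np.pi * k) / 3.0) - an / 3.0
            ok = (cand > 0) & (cand <= 1.0 + 1e-9) & ~np.isfinite(best)
            best = np.where(ok, cand, best)
        u[~pos] = best

    for _ in range(newton_steps):
        g = 4.0 * u**3 + (4.0 * f - 3.0) * u**2 - 1.0
        gp = 12.0 * u**2 + 2.0 * (4.0 * f - 3.0) * u
        u = u - g / gp

    u = np.clip(u, 1e-15, 1.0)
    l = 1.0 - u
    return float(l[0]) if scalar else l


def _ms_slope(l: np.ndarray) -> np.ndarray:
    """d f / d l of the Marko-Siggia backbone."""
    return 1.0 / (2.0 * (1.0 - l) ** 3) + 1.0


# ---------------------------------------------------------------------------
# ssDNA segment
# ---------------------------------------------------------------------------

def ms_wlc_force(x, ss: SsParams, th: ThermalContext = ThermalContext()):
    """Marko-Siggia WLC force (pN) of an ssDNA segment at extension ``x`` nm.

    Strictly increasing in ``x`` and divergent as x -> contour length.
    """
    x_arr = np.asarray(x, dtype=float)
    if ss.contour_length == 0:
        raise ValueError("zero-length ssDNA segment carries no entropic force")
    if np.any(x_arr < 0) or np.any(x_arr >= ss.contour_length):
        raise ValueError("extension must satisfy 0 <= x < contour_length")
    l = x_arr / ss.contour_length
    out = th.kBT / ss.persistence_length * _ms_reduced_force(l)
    return float(out) if np.ndim(x) == 0 else out


def ss_wlc_extension(F, ss: SsParams, th: ThermalContext = ThermalContext()):
    """Extension (nm) of an ssDNA segment at force ``F`` pN (exact inversion)."""
    F_arr = np.asarray(F, dtype=float)
    if np.any(F_arr < 0):
        raise ValueError("force must be >= 0")
    if ss.contour_length == 0:
        out = np.zeros_like(F_arr)
        return float(out) if np.ndim(F) == 0 else out
    f = F_arr * ss.persistence_length / th.kBT
    out = ss.contour_length * _ms_fractional_extension(f)
    return float(out) if np.ndim(F) == 0 else out


# ---------------------------------------------------------------------------
# dsDNA segment (extensible WLC)
# ---------------------------------------------------------------------------

def ext_wlc_extension(F, ds: DsParams, th: ThermalContext = ThermalContext()):
    """Extension (nm) of an extensible-WLC dsDNA segment at force ``F`` pN.

    With the effective fractional extension l = x/Lc - F/K the implicit
    extensible WLC reduces to the Marko-Siggia cubic in l, so the
    inversion is the Cardano root followed by x = Lc (l + F/K).
    """
    F_arr = np.asarray(F, dtype=float)
    if np.any(F_arr < 0):
        raise ValueError("force must be >= 0")
    f = F_arr * ds.persistence_length / th.kBT
    l = _ms_fractional_extension(f)
    out = ds.contour_length * (l + F_arr / ds.stretch_modulus)
    return float(out) if np.ndim(F) == 0 else out


def ext_wlc_force(x: float, ds: DsParams, th: ThermalContext = ThermalContext(),
                  f_hi: float = 1e6) -> float:
    """Force (pN) of an extensible-WLC dsDNA segment at extension ``x`` nm.

    The extensible WLC is implicit in F (the force enters the enthalpic
    term); the unique nonnegative root is found numerically.
    """
    if x < 0:
        raise ValueError("extension must be >= 0")
    if x == 0:
        return 0.0
    hi = 1.0
    while ext_wlc_extension(hi, ds, th) < x:
        hi *= 4.0
        if hi > f_hi:
            raise ValueError(
                f"no WLC solution at x = {x} nm (beyond enthalpic limit)")
    return brentq(lambda F: ext_wlc_extension(F, ds, th) - x, 0.0, hi,
                  xtol=1e-12, rtol=1e-15)


# ---------------------------------------------------------------------------
# Hybrid (series) tether
# ---------------------------------------------------------------------------

def hybrid_extension(F, state: ConstructState,
                     th: ThermalContext = ThermalContext()):
    """Total tether extension (nm): dsDNA + ssDNA + rigid offsets, in series."""
    F_arr = np.asarray(F, dtype=float)
    out = ext_wlc_extension(F_arr, state.ds, th) + state.offset_total
    if state.ss.contour_length > 0:
        out = out + ss_wlc_extension(F_arr, state.ss, th)
    return float(out) if np.ndim(F) == 0 else out


def hybrid_compliance(F, state: ConstructState,
                      th: ThermalContext = ThermalContext()):
    """dx/dF (nm/pN) of the hybrid tether; analytic, used by Newton solvers."""
    F_arr = np.asarray(F, dtype=float)
    f_ds = F_arr * state.ds.persistence_length / th.kBT
    l_ds = _ms_fractional_extension(f_ds)
    out = state.ds.contour_length * (
        state.ds.persistence_length / th.kBT / _ms_slope(l_ds)
        + 1.0 / state.ds.stretch_modulus)
    if state.ss.contour_length > 0:
        f_ss = F_arr * state.ss.persistence_length / th.kBT
        l_ss = _ms_fractional_extension(f_ss)
        out = out + state.ss.contour_length * (
            state.ss.persistence_length / th.kBT / _ms_slope(l_ss))
    return float(out) if np.ndim(F) == 0 else out


def hybrid_force(x: float, state: ConstructState,
                 th: ThermalContext = ThermalContext()) -> float:
    """Force (pN) at total extension ``x`` nm of the hybrid tether."""
    if x < state.offset_total:
        raise ValueError(
            f"extension {x} nm below rigid offset total {state.offset_total} nm")
    if x == state.offset_total:
        return 0.0
    hi = 1.0
    while hybrid_extension(hi, state, th) < x:
        hi *= 4.0
        if hi > 1e6:
            raise ValueError(f"no hybrid WLC solution at x = {x} nm")
    return brentq(lambda F: hybrid_extension(F, state, th) - x, 0.0, hi,
                  xtol=1e-12, rtol=1e-15)


# ---------------------------------------------------------------------------
# Contour-length arithmetic and fitting
# ---------------------------------------------------------------------------

def expected_contour_change(state_a: ConstructState,
                            state_b: ConstructState) -> float:
    """Designed contour-length change (nm) between two states of one molecule.

    Released ssDNA contributes its contour length; folded elements
    contribute their rigid end-to-end offsets.  For synaptic-complex
    disassembly the arithmetic is (114 nt x 0.68 nm/nt + 2 x 2 nm) -
    10.5 nm = 71 nm.
    """
    return state_b.contour_coordinate - state_a.contour_coordinate


@dataclass
class SegmentFit:
    """Result of fitting free contour lengths to one FEC segment."""

    state: ConstructState
    rms_residual: float
    success: bool
    message: str = ""

    @property
    def contour_coordinate(self) -> float:
        return self.state.contour_coordinate


def fit_segment_contour(points, template: ConstructState,
                        free: tuple[str, ...] = ("ss",),
                        th: ThermalContext = ThermalContext()) -> SegmentFit:
    """Least-squares fit of free contour lengths to (extension, force) points.

    ``points`` is an (n, 2) array of (extension nm, force pN); ``free``
    names the contour lengths allowed to vary ("ss", "ds").  Residuals
    are extension mismatches at the measured forces.  Requires at least
    5 points spanning at least 2 pN.  Non-convergence is reported via
    ``success=False`` rather than raised.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (extension, force)")
    x_meas, f_meas = pts[:, 0], pts[:, 1]
    if len(pts) < 5:
        raise ValueError("need at least 5 points to fit a segment")
    if np.ptp(f_meas) < 2.0:
        raise ValueError("points must span at least 2 pN of force")
    if not free:
        raise ValueError("at least one free contour length required")

    def build(params: np.ndarray) -> ConstructState:
        state = template
        i = 0
        if "ss" in free:
            state = replace(state, ss=replace(state.ss, contour_length=max(params[i], 0.0)))
            i += 1
        if "ds" in free:
            state = replace(state, ds=replace(state.ds, contour_length=max(params[i], 1e-6)))
        return state

    p0, lo, hi = [], [], []
    if "ss" in free:
        p0.append(max(template.ss.contour_length, 1.0))
        lo.append(0.0)
        hi.append(np.inf)
    if "ds" in free:
        p0.append(template.ds.contour_length)
        lo.append(1e-6)
        hi.append(np.inf)

    def resid(params: np.ndarray) -> np.ndarray:
        return hybrid_extension(f_meas, build(params), th) - x_meas

    try:
        sol = least_squares(resid, p0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12)
    except Exception as exc:  # pragma: no cover - scipy failure path
        return SegmentFit(template, math.inf, False, str(exc))
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return SegmentFit(build(sol.x), rms, bool(sol.success),
                      "" if sol.success else sol.message)


# ---------------------------------------------------------------------------
# Standard tether states
# ---------------------------------------------------------------------------

def tether_states(handle_bp: float = 5000,
                  spacer_nt: float = 114,
                  hairpin_nt: tuple[float, ...] = (63, 63),
                  synapse_offset_nm: float = 10.5,
                  hairpin_offset_nm: float = 2.0,
                  delta_L_sub_nm: float = 44.6,
                  ds_persistence_nm: float = 45.0,
                  ds_stretch_modulus_pN: float = 1200.0,
                  ss_persistence_nm: float = 2.0,
                  ss_rise_nm_per_nt: float = SS_RISE_NM_PER_NT,
                  ds_rise_nm_per_bp: float = DS_RISE_NM_PER_BP,
                  ) -> dict[str, ConstructState]:
    """Build the canonical state set of the double-hairpin tether.

    States, in disassembly order:

    * ``synapse``       - assembled synaptic complex; the spacer and both
      hairpins are sequestered into one rigid 10.5-nm element.
    * ``substate``      - intermediate after disassembly in which part of
      the spacer remains constrained; its ssDNA contour is chosen so the
      contour change from ``synapse`` equals ``delta_L_sub_nm``.
    * ``hairpin_bound`` - stretched spacer between two folded (2 nm)
      hairpins.
    * ``unfolded``      - spacer plus both unfolded hairpins as ssDNA.
    """
    ds = DsParams(ds_contour := ds_contour_from_bp(handle_bp, ds_rise_nm_per_bp),
                  ds_persistence_nm, ds_stretch_modulus_pN)
    del ds_contour
    pss = ss_persistence_nm
    rise = ss_rise_nm_per_nt
    spacer = ss_contour_from_nt(spacer_nt, rise)
    hp_offsets = tuple((f"hairpin_{i}", hairpin_offset_nm)
                       for i in range(len(hairpin_nt)))
    n_hp = len(hairpin_nt)
    sub_ss = delta_L_sub_nm + synapse_offset_nm - n_hp * hairpin_offset_nm
    if sub_ss < 0:
        raise ValueError("delta_L_sub too small for the given offsets")
    common = dict(ss_rise_per_nt=rise, ds_rise_per_bp=ds_rise_nm_per_bp)
    return {
        "synapse": ConstructState(
            ds, SsParams(0.0, pss), (("synapse", synapse_offset_nm),),
            label="synapse", **common),
        "substate": ConstructState(
            ds, SsParams(sub_ss, pss), hp_offsets, label="substate", **common),
        "hairpin_bound": ConstructState(
            ds, SsParams(spacer, pss), hp_offsets, label="hairpin_bound",
            **common),
        "unfolded": ConstructState(
            ds, SsParams(spacer + sum(ss_contour_from_nt(n, rise)
                                      for n in hairpin_nt), pss),
            (), label="unfolded", **common),
    }


#: disassembly order used for deterministic tie-breaking in state assignment
STATE_ORDER = ("synapse", "substate", "hairpin_bound", "unfolded")
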