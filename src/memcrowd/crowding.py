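"""Entropic tensions in crowded membranes.

Biological membranes are so densely packed with proteins (area fractions of
20-55% are typical) that excluded-area interactions between them shift the
free-energy balance of any conformational transition that changes a protein's
in-plane footprint.  This module models the crowding proteins as a fluid of
hard disks and the switching protein (the case study is the bacterial
mechanosensitive channel MscL, opening from radius 2.4 nm to 3.5 nm) as a
disk that changes radius.  Crowding then enters the gating free energy
through two effective tensions:

* an entropic *surface* tension ``sigma_c`` conjugate to the channel's area
  change ``dA = pi*(Ro^2 - Rc^2)``, and
* an entropic *line* tension ``tau_c`` conjugate to the circumference change
  ``dC = 2*pi*(Ro - Rc)``, which arises because the annulus of excluded
  area around the channel (width = crowder radius) grows with the channel.

Two levels of theory are provided.  The dilute "ideal gas" estimate gives
``sigma_c = c`` and ``tau_c = c*<r>`` (energies in kBT, lengths in nm, so
``beta = 1`` throughout).  Scaled-particle theory (SPT) for hard-disk
mixtures resums the overlapping exclusion zones and gives

    sigma_c = c * [ 1/(1-phi) + phi/((1+delta2)*(1-phi)^2) ]
    tau_c   = c * <r> / (1-phi)

with ``c`` the crowder number density, ``phi = c*pi*<r^2>`` the area
fraction and ``delta2 = (<r^2>-<r>^2)/<r>^2`` the relative radius variance.
At phi = 0.5 (uniform crowders) SPT enhances the surface and line tensions
by factors of four and two over the ideal gas.

Two thermodynamic ensembles are supported.  At constant total membrane area
both tensions contribute, ``dG_crowd = sigma_c*dA + tau_c*dC``.  At constant
applied tension the membrane area grows with the channel so that lipid area
is conserved; the surface-tension term cancels and only the line tension
survives, ``dG_crowd = tau_c*dC``, alongside the loading-device relaxation
``-sigma*dA``.

An independent hard-disk Metropolis Monte Carlo + Widom test-particle
insertion oracle (periodic box, minimum image) validates the SPT insertion
free energies numerically.

Sections below follow the order the method runs: configuration defaults,
the crowder mixture model, entropic tensions (ideal gas and SPT), gating
energetics and open-probability curves, the Monte Carlo oracle, and file
I/O / fixture generation.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

logger = logging.getLogger("memcrowd")

# --------------------------------------------------------------------------
# Configuration defaults
# --------------------------------------------------------------------------

#: Default in-plane area of a single transmembrane helix (nm^2).
DEFAULT_HELIX_FOOTPRINT_NM2 = 1.4

#: Above this area fraction the hard-disk SPT equation of state is known to
#: degrade on approach to close packing; constructions log a warning.
SPT_PACKING_WARNING_PHI = 0.78

Model = Literal["ideal_gas", "spt"]
Ensemble = Literal["constant_area", "constant_tension"]

__all__ = [
    "DEFAULT_HELIX_FOOTPRINT_NM2",
    "SPT_PACKING_WARNING_PHI",
    "CrowderMixture",
    "TMHelixTable",
    "radius_from_tm_helices",
    "mixture_moments",
    "delta2_from_tm_distribution",
    "area_fraction",
    "concentration_for_fraction",
    "mass_ratio_to_area_fraction",
    "EntropicTensions",
    "BoxGeometry",
    "ig_single_crowder_entropy",
    "ig_tensions",
    "spt_tensions",
    "spt_surface_tension",
    "spt_line_tension",
    "spt_excess_chemical_potential",
    "spt_area_change_free_energy",
    "tensions_for",
    "ChannelGeometry",
    "GatingResult",
    "geometry_deltas",
    "gating_energy_constant_area",
    "gating_energy_constant_tension",
    "constant_tension_decomposition_check",
    "gating_tension_shift",
    "open_probability",
    "popen_midpoint",
    "DiskConfiguration",
    "McSettings",
    "init_configuration",
    "run_metropolis",
    "widom_insertion_probability",
    "exact_free_area_one_crowder",
    "grid_free_area_one_crowder",
    "read_tm_table",
    "mixture_from_config",
    "mixture_to_config",
    "gating_table",
    "popen_curve_table",
    "tensions_table",
    "mixture_stats_table",
    "generate_fixture",
]


# --------------------------------------------------------------------------
# Crowder mixture model
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CrowderMixture:
    """A hard-disk model of the crowding membrane proteins.

    Parameters
    ----------
    radii
        In-plane disk radii in nm, each > 0.
    abundances
        Relative weights (unitless, >= 0, not all zero).  They are used as
        a discrete probability distribution over species; normalisation is
        internal, so any positive rescaling describes the same mixture.
    concentration
        Total areal number density ``c`` of crowders in nm^-2.

    The derived area fraction ``phi = c*pi*<r^2>`` must lie in [0, 1);
    construction fails for phi >= 1 (over-packed) and logs a warning above
    ``SPT_PACKING_WARNING_PHI`` where SPT loses accuracy.
    """

    radii: tuple[float, ...]
    abundances: tuple[float, ...]
    concentration: float

    def __post_init__(self) -> None:
        radii = tuple(float(r) for r in self.radii)
        weights = tuple(float(w) for w in self.abundances)
        if len(radii) == 0:
            raise ValueError("mixture needs at least one species")
        if len(radii) != len(weights):
            raise ValueError("radii and abundances must have equal length")
        if any(r <= 0 for r in radii):
            raise ValueError("all radii must be positive")
        if any(w < 0 for w in weights):
            raise ValueError("abundances must be nonnegative")
        if not any(w > 0 for w in weights):
            raise ValueError("abundances must not all be zero")
        if not (self.concentration >= 0) or not math.isfinite(self.concentration):
            raise ValueError("concentration must be finite and >= 0")
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "abundances", weights)
        object.__setattr__(self, "concentration", float(self.concentration))
        phi = self.area_fraction
        if phi >= 1.0:
            raise ValueError(
                f"unphysical packing: area fraction phi = {phi:.3f} >= 1"
            )
        if phi > SPT_PACKING_WARNING_PHI:
            logger.warning(
                "area fraction %.3f approaches close packing; "
                "SPT accuracy degrades above %.2f",
                phi,
                SPT_PACKING_WARNING_PHI,
            )

    # -- derived moments ---------------------------------------------------

    @property
    def weights(self) -> np.ndarray:
        """Normalised species probabilities."""
        w = np.asarray(self.abundances, dtype=float)
        return w / w.sum()

    @property
    def mean_radius(self) -> float:
        """Abundance-weighted <r> in nm."""
        return float(self.weights @ np.asarray(self.radii))

    @property
    def mean_sq_radius(self) -> float:
        """Abundance-weighted <r^2> in nm^2."""
        return float(self.weights @ np.asarray(self.radii) ** 2)

    @property
    def radius_variance(self) -> float:
        """s^2 = <r^2> - <r>^2 in nm^2 (clipped at 0 against roundoff)."""
        return max(self.mean_sq_radius - self.mean_radius**2, 0.0)

    @property
    def delta2(self) -> float:
        """Relative radius variance s^2/<r>^2 (unitless, >= 0)."""
        return self.radius_variance / self.mean_radius**2

    @property
    def area_fraction(self) -> float:
        """phi = c*pi*<r^2>."""
        return self.concentration * math.pi * self.mean_sq_radius

    # -- constructors ------------------------------------------------------

    @classmethod
    def uniform(
        cls,
        radius: float,
        *,
        concentration: float | None = None,
        area_fraction: float | None = None,
    ) -> "CrowderMixture":
        """Single-species mixture from either ``c`` or ``phi`` (exactly one)."""
        if (concentration is None) == (area_fraction is None):
            raise ValueError("give exactly one of concentration / area_fraction")
        if concentration is None:
            concentration = concentration_for_fraction(area_fraction, radius**2)
        return cls((float(radius),), (1.0,), concentration)

    @classmethod
    def from_tm_table(
        cls,
        table: "TMHelixTable",
        *,
        helix_footprint: float = DEFAULT_HELIX_FOOTPRINT_NM2,
        concentration: float | None = None,
        area_fraction: float | None = None,
    ) -> "CrowderMixture":
        """Build a mixture from a TM-helix-count abundance table.

        Each protein with ``n`` helices becomes a disk of radius
        ``sqrt(n*helix_footprint/pi)`` (area proportional to helix count).
        """
        if (concentration is None) == (area_fraction is None):
            raise ValueError("give exactly one of concentration / area_fraction")
        radii = tuple(
            radius_from_tm_helices(n, helix_footprint) for n in table.n_helices
        )
        weights = tuple(table.weights)
        if concentration is None:
            w = np.asarray(weights) / np.sum(weights)
            m2 = float(w @ np.asarray(radii) ** 2)
            concentration = concentration_for_fraction(area_fraction, m2)
        return cls(radii, weights, concentration)


@dataclass(frozen=True)
class TMHelixTable:
    """Rows of (number of TM helices, relative abundance).

    Proteins with zero predicted TM helices are not membrane-embedded and
    are rejected.
    """

    n_helices: tuple[int, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        ns = tuple(int(n) for n in self.n_helices)
        ws = tuple(float(w) for w in self.weights)
        if len(ns) == 0:
            raise ValueError("TM-helix table is empty")
        if len(ns) != len(ws):
            raise ValueError("n_helices and weights must have equal length")
        if any(n < 1 for n in ns):
            raise ValueError("proteins with no TM helices are excluded (n >= 1)")
        if any(w < 0 for w in ws):
            raise ValueError("abundances must be nonnegative")
        if not any(w > 0 for w in ws):
            raise ValueError("at least one row must have positive abundance")
        object.__setattr__(self, "n_helices", ns)
        object.__setattr__(self, "weights", ws)


def radius_from_tm_helices(
    n_helices: int, helix_footprint: float = DEFAULT_HELIX_FOOTPRINT_NM2
) -> float:
    """Disk radius (nm) of a protein with ``n_helices`` transmembrane helices.

    The protein is modelled as a disk whose area is the helix count times the
    per-helix footprint, i.e. ``r = sqrt(n*a_helix/pi)`` — the r ∝ sqrt(n)
    rule.  ``n_helices`` must be >= 1 (zero-TM proteins are excluded).
    """
    if int(n_helices) < 1:
        raise ValueError("n_helices must be >= 1 (zero-TM proteins excluded)")
    if not helix_footprint > 0:
        raise ValueError("helix_footprint must be positive")
    return math.sqrt(int(n_helices) * helix_footprint / math.pi)


def mixture_moments(mixture: CrowderMixture) -> tuple[float, float, float]:
    """Return (<r>, <r^2>, delta2) of the crowder radius distribution."""
    return mixture.mean_radius, mixture.mean_sq_radius, mixture.delta2


def delta2_from_tm_distribution(table: TMHelixTable) -> float:
    """Relative radius variance implied by a TM-helix-count distribution.

    With r ∝ sqrt(n), delta2 = <n>/<sqrt(n)>^2 - 1, independent of the
    per-helix footprint and of any rescaling of the abundances.
    """
    w = np.asarray(table.weights, dtype=float)
    w = w / w.sum()
    n = np.asarray(table.n_helices, dtype=float)
    mean_n = float(w @ n)
    mean_sqrt_n = float(w @ np.sqrt(n))
    return mean_n / mean_sqrt_n**2 - 1.0


def area_fraction(concentration: float, mean_r2: float) -> float:
    """phi = c*pi*<r^2>; raises for phi >= 1 (unphysical packing)."""
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    phi = concentration * math.pi * mean_r2
    if phi >= 1.0:
        raise ValueError(f"unphysical packing: phi = {phi:.3f} >= 1")
    return phi


def concentration_for_fraction(phi: float, mean_r2: float) -> float:
    """Inverse of :func:`area_fraction`: c = phi/(pi*<r^2>)."""
    if not (0.0 <= phi < 1.0):
        raise ValueError("area fraction must lie in [0, 1)")
    if not mean_r2 > 0:
        raise ValueError("mean squared radius must be positive")
    return phi / (math.pi * mean_r2)


def mass_ratio_to_area_fraction(
    protein_lipid_mass_ratio: float, tm_mass_fraction: float = 0.5
) -> float:
    """Protein area fraction from a protein:lipid mass ratio.

    Assuming transmembrane domains make up a fraction ``f`` of membrane
    protein mass and have the same density as the lipids, the in-plane area
    fraction is ``phi = f*m/(f*m + 1)``.  The physiological mass-ratio range
    1-2.5 with f = 0.5 maps to phi of roughly 0.33-0.56.
    """
    if protein_lipid_mass_ratio < 0:
        raise ValueError("mass ratio must be >= 0")
    if not (0.0 <= tm_mass_fraction <= 1.0):
        raise ValueError("TM mass fraction must lie in [0, 1]")
    fm = tm_mass_fraction * protein_lipid_mass_ratio
    return fm / (fm + 1.0)


# --------------------------------------------------------------------------
# Entropic tensions: ideal gas and scaled-particle theory
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class EntropicTensions:
    """Crowding-induced (surface, line) tension pair.

    ``surface_tension`` in kBT/nm^2, ``line_tension`` in kBT/nm, both
    reported as positive magnitudes opposing channel opening; ``model`` tags
    the level of theory.
    """

    surface_tension: float
    line_tension: float
    model: Model


@dataclass(frozen=True)
class BoxGeometry:
    """A square hard-wall membrane patch with a lattice-entropy length scale.

    ``side_length`` L in nm; ``discretization_length`` b in nm is the lattice
    constant of the free-area entropy ln(A_free/b^2).  b cancels from all
    entropy *differences*, which is all that enters gating energetics.
    """

    side_length: float
    discretization_length: float = 1.0

    def __post_init__(self) -> None:
        if not self.side_length > 0:
            raise ValueError("box side length must be positive")
        if not self.discretization_length > 0:
            raise ValueError("discretization length must be positive")


def ig_single_crowder_entropy(
    box: BoxGeometry, channel_radius: float, crowder_radius: float
) -> float:
    """Translational entropy (units of kB) of one crowder in a hard-wall box.

    The crowder's center of mass is excluded from a band of width r along
    the box edge and from a disk of radius R+r around the centered channel:
    S = ln( [(L-2r)^2 - pi*(R+r)^2] / b^2 ).
    """
    if channel_radius < 0 or crowder_radius < 0:
        raise ValueError("radii must be >= 0")
    L = box.side_length
    free_area = (L - 2 * crowder_radius) ** 2 - math.pi * (
        channel_radius + crowder_radius
    ) ** 2
    if free_area <= 0:
        raise ValueError("box too small: no free area for the crowder center")
    return math.log(free_area / box.discretization_length**2)


def ig_tensions(mixture: CrowderMixture) -> EntropicTensions:
    """Ideal-gas (dilute-limit) tensions: sigma_c = c, tau_c = c*<r>.

    The surface tension is the 2D ideal-gas law; the line tension comes from
    the exclusion annulus of width <r> around the channel and vanishes as
    the crowder size goes to zero.
    """
    c = mixture.concentration
    return EntropicTensions(c, c * mixture.mean_radius, "ideal_gas")


def spt_surface_tension(mixture: CrowderMixture) -> float:
    """SPT surface tension of a hard-disk mixture, kBT/nm^2.

    sigma_c = c*[1/(1-phi) + phi/((1+delta2)*(1-phi)^2)].  For uniform
    crowders (delta2 = 0) this reduces to c/(1-phi)^2; size variability
    (delta2 > 0) strictly lowers sigma_c at fixed c and phi.
    """
    c = mixture.concentration
    phi = mixture.area_fraction
    d2 = mixture.delta2
    return c * (1.0 / (1.0 - phi) + phi / ((1.0 + d2) * (1.0 - phi) ** 2))


def spt_line_tension(mixture: CrowderMixture) -> float:
    """SPT line tension tau_c = c*<r>/(1-phi), kBT/nm."""
    return mixture.concentration * mixture.mean_radius / (1.0 - mixture.area_fraction)


def spt_tensions(mixture: CrowderMixture) -> EntropicTensions:
    """Both SPT tensions as an :class:`EntropicTensions` record."""
    return EntropicTensions(
        spt_surface_tension(mixture), spt_line_tension(mixture), "spt"
    )


def tensions_for(mixture: CrowderMixture, model: Model) -> EntropicTensions:
    """Dispatch on the level of theory."""
    if model == "ideal_gas":
        return ig_tensions(mixture)
    if model == "spt":
        return spt_tensions(mixture)
    raise ValueError(f"unknown model {model!r}; use 'ideal_gas' or 'spt'")


def spt_excess_chemical_potential(
    test_radius: float, mixture: CrowderMixture
) -> float:
    """SPT excess chemical potential (kBT) of a test disk of radius R.

    mu_ex(R) = -ln(1-phi) + 2*pi*c*<r>*R/(1-phi) + pi*R^2*sigma_spt.
    ``exp(-mu_ex)`` is the probability that the test disk can be inserted at
    a uniformly random position without overlapping any crowder (the Widom
    identity); at R = 0 this is exactly the free-area fraction 1-phi.
    """
    if test_radius < 0:
        raise ValueError("test radius must be >= 0")
    phi = mixture.area_fraction
    c = mixture.concentration
    return (
        -math.log1p(-phi)
        + 2.0 * math.pi * c * mixture.mean_radius * test_radius / (1.0 - phi)
        + math.pi * test_radius**2 * spt_surface_tension(mixture)
    )


def spt_area_change_free_energy(
    area_from: float,
    area_to: float,
    radii: Sequence[float],
    copy_numbers: Sequence[float],
) -> float:
    """Free-energy change (kBT) of compressing/expanding a hard-disk mixture.

    Closed form of the integral of the SPT equation of state over area at
    fixed copy numbers n_i.  With N = sum(n_i), B = pi*sum(n_i*r_i^2)
    (occupied area) and C = pi*(sum(n_i*r_i))^2:

        dF = -[ N*ln((A2-B)/(A1-B)) - C*(1/(A2-B) - 1/(A1-B)) ]

    so the crowders' free energy decreases as the area grows, and
    -dF/dA2 equals the SPT surface tension at the final state.  Both areas
    must exceed the occupied area B.
    """
    n = np.asarray(copy_numbers, dtype=float)
    r = np.asarray(radii, dtype=float)
    if n.shape != r.shape:
        raise ValueError("radii and copy_numbers must have equal length")
    if (n < 0).any():
        raise ValueError("copy numbers must be >= 0")
    N = float(n.sum())
    B = math.pi * float(n @ r**2)
    C = math.pi * float(n @ r) ** 2
    if area_from <= B or area_to <= B:
        raise ValueError(
            f"over-packed: areas must exceed the occupied area B = {B:.6g} nm^2"
        )
    return -(
        N * math.log((area_to - B) / (area_from - B))
        - C * (1.0 / (area_to - B) - 1.0 / (area_from - B))
    )


# --------------------------------------------------------------------------
# Gating energetics and open-probability curves
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ChannelGeometry:
    """Closed/open in-plane radii (nm) of the gating protein.

    For an opening transition R_o > R_c; a closing transition is allowed and
    flips the signs of the derived changes dA and dC.
    """

    closed_radius: float
    open_radius: float

    def __post_init__(self) -> None:
        if not (self.closed_radius > 0 and self.open_radius > 0):
            raise ValueError("channel radii must be positive")

    @property
    def delta_area(self) -> float:
        """dA = pi*(Ro^2 - Rc^2), nm^2."""
        return math.pi * (self.open_radius**2 - self.closed_radius**2)

    @property
    def delta_circumference(self) -> float:
        """dC = 2*pi*(Ro - Rc), nm."""
        return 2.0 * math.pi * (self.open_radius - self.closed_radius)


def geometry_deltas(channel: ChannelGeometry) -> tuple[float, float]:
    """Return (dA, dC) for the gating transition."""
    return channel.delta_area, channel.delta_circumference


@dataclass(frozen=True)
class GatingResult:
    """Decomposed gating free-energy change, all energies in kBT.

    ``crowding_energy`` is the entropic cost exerted by the crowders;
    ``loading_energy`` is the loading-device relaxation -sigma*dA (zero in
    the constant-area ensemble); ``total`` is their sum.
    ``gating_tension_shift`` = crowding_energy/dA (kBT/nm^2) is the upward
    shift of the midpoint tension measurable in patch clamp; it is NaN for a
    degenerate transition with dA = 0.
    """

    crowding_energy: float
    loading_energy: float
    total: float
    gating_tension_shift: float
    ensemble: Ensemble
    model: Model
    delta_area: float
    delta_circumference: float


def _result(
    crowding: float,
    loading: float,
    ensemble: Ensemble,
    model: Model,
    channel: ChannelGeometry,
) -> GatingResult:
    dA = channel.delta_area
    shift = crowding / dA if dA != 0.0 else math.nan
    return GatingResult(
        crowding_energy=crowding,
        loading_energy=loading,
        total=crowding + loading,
        gating_tension_shift=shift,
        ensemble=ensemble,
        model=model,
        delta_area=dA,
        delta_circumference=channel.delta_circumference,
    )


def gating_energy_constant_area(
    channel: ChannelGeometry, mixture: CrowderMixture, model: Model = "spt"
) -> GatingResult:
    """Crowding contribution to gating at fixed total membrane area.

    Both tensions act: dG_crowd = sigma_c*dA + tau_c*dC.  There is no
    loading device, so the total equals the crowding term.
    """
    t = tensions_for(mixture, model)
    crowding = (
        t.surface_tension * channel.delta_area
        + t.line_tension * channel.delta_circumference
    )
    return _result(crowding, 0.0, "constant_area", model, channel)


def gating_energy_constant_tension(
    channel: ChannelGeometry,
    mixture: CrowderMixture,
    applied_tension: float = 0.0,
    model: Model = "spt",
) -> GatingResult:
    """Crowding contribution to gating at fixed applied tension sigma.

    The membrane area grows with the channel so that lipid area is
    conserved; the surface-tension term cancels and only the line tension
    survives: dG_crowd = tau_c*dC.  The loading device relaxes by
    -sigma*dA, so total = tau_c*dC - sigma*dA (tension favors opening).
    """
    t = tensions_for(mixture, model)
    crowding = t.line_tension * channel.delta_circumference
    loading = -applied_tension * channel.delta_area
    return _result(crowding, loading, "constant_tension", model, channel)


def constant_tension_decomposition_check(
    channel: ChannelGeometry,
    mixture: CrowderMixture,
    applied_tension: float = 0.0,
    total_area: float = 1.0e6,
) -> float:
    """Residual between the stepwise and closed-form constant-tension routes.

    The stepwise route removes a closed channel at total area A, expands the
    crowder-only membrane by dA (conserving lipid area), and inserts an open
    channel at A + dA, each step using the full SPT chemical potentials and
    the exact area integral of the equation of state; the loading device
    contributes -sigma*dA.  The closed-form route is the leading-order
    result tau_c*dC - sigma*dA.  The residual is O(1/A): it vanishes as the
    membrane grows at fixed composition, and is exactly the ideal-gas zero
    when there are no crowders.
    """
    dA = channel.delta_area
    total_N = mixture.concentration * total_area
    counts = mixture.weights * total_N
    radii = np.asarray(mixture.radii)

    def at_area(a: float) -> CrowderMixture:
        return replace(mixture, concentration=total_N / a)

    a_closed = total_area
    a_open = total_area + dA
    stepwise = (
        -spt_excess_chemical_potential(channel.closed_radius, at_area(a_closed))
        + spt_area_change_free_energy(a_closed, a_open, radii, counts)
        + spt_excess_chemical_potential(channel.open_radius, at_area(a_open))
        - applied_tension * dA
    )
    closed_form = (
        spt_line_tension(mixture) * channel.delta_circumference
        - applied_tension * dA
    )
    return stepwise - closed_form


def gating_tension_shift(result: GatingResult) -> float:
    """Crowding-induced increase of the gating tension, kBT/nm^2.

    The midpoint of the open-probability curve moves up by
    crowding_energy/dA; raises for a degenerate transition with dA = 0.
    """
    if result.delta_area == 0.0:
        raise ValueError("gating tension shift undefined for dA = 0")
    return result.crowding_energy / result.delta_area


def _line_tension(mixture: CrowderMixture | None, model: Model) -> float:
    if mixture is None:
        return 0.0
    return tensions_for(mixture, model).line_tension


def open_probability(
    applied_tension: float | np.ndarray,
    gating_tension: float,
    channel: ChannelGeometry,
    mixture: CrowderMixture | None = None,
    model: Model = "spt",
) -> float | np.ndarray:
    """Two-state open probability at a given applied tension (kBT/nm^2).

    All non-crowding contributions to the gating free energy are lumped into
    the bare gating tension sigma*_0, so in the constant-tension ensemble

        dG(sigma) = (sigma*_0 - sigma)*dA + tau_c*dC
        P_open    = 1/(1 + exp(dG))        (energies in kBT).

    Without crowders (``mixture=None``) the midpoint sits at sigma*_0; with
    crowders it shifts up by tau_c*dC/dA, the gating-tension shift.
    """
    tau = _line_tension(mixture, model)
    sigma = np.asarray(applied_tension, dtype=float)
    dg = (gating_tension - sigma) * channel.delta_area + tau * channel.delta_circumference
    p = expit(-dg)
    return float(p) if np.isscalar(applied_tension) else p


def popen_midpoint(
    gating_tension: float,
    channel: ChannelGeometry,
    mixture: CrowderMixture | None = None,
    model: Model = "spt",
) -> float:
    """Applied tension at which P_open = 1/2: sigma*_0 + tau_c*dC/dA."""
    tau = _line_tension(mixture, model)
    return gating_tension + tau * channel.delta_circumference / channel.delta_area


# --------------------------------------------------------------------------
# Monte Carlo / Widom-insertion oracle
# --------------------------------------------------------------------------


@dataclass
class DiskConfiguration:
    """A snapshot of hard disks in a periodic square box.

    ``centers`` is an (N, 2) array of positions in [0, box_side)^2; overlap
    is judged with the minimum-image distance, so the configuration tiles
    the plane.
    """

    box_side: float
    centers: np.ndarray
    radii: np.ndarray

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.radii = np.asarray(self.radii, dtype=float).ravel()
        if self.centers.size == 0:
            self.centers = self.centers.reshape(0, 2)

    @property
    def n_disks(self) -> int:
        return len(self.radii)

    def has_overlap(self) -> bool:
        """True if any pair of disks overlaps under minimum image."""
        x = self.centers
        if len(x) < 2:
            return False
        d = x[:, None, :] - x[None, :, :]
        d -= self.box_side * np.round(d / self.box_side)
        dist2 = (d**2).sum(axis=-1)
        thresh = (self.radii[:, None] + self.radii[None, :]) ** 2
        np.fill_diagonal(dist2, np.inf)
        return bool((dist2 < thresh).any())


@dataclass
class McSettings:
    """Run-length and move parameters for the Metropolis sampler.

    ``max_step`` is the half-width (nm) of the uniform displacement move; if
    None it is auto-tuned toward ~40% acceptance during equilibration and
    then frozen.  One sweep = N single-disk move attempts.
    """

    n_sweeps: int = 2000
    n_equilibration: int = 500
    max_step: float | None = None
    seed: int = 0
    n_insertions_per_sample: int = 2000
    sample_interval: int = 10

    def __post_init__(self) -> None:
        if min(self.n_sweeps, self.n_equilibration, self.sample_interval) < 1:
            raise ValueError("sweep counts and sample interval must be positive")
        if self.n_insertions_per_sample < 1:
            raise ValueError("n_insertions_per_sample must be positive")
        if self.max_step is not None and not self.max_step > 0:
            raise ValueError("max_step must be positive")


def init_configuration(
    box_side: float,
    mixture: CrowderMixture,
    target_n: int,
    seed: int,
    max_attempts_per_disk: int = 10_000,
) -> DiskConfiguration:
    """Random-sequential-insertion start with composition drawn from the mixture.

    Deterministic for a fixed seed.  Random insertion becomes infeasible
    near the RSA jamming density, so packings with phi >= 0.7 in the
    requested box are rejected up front.
    """
    if target_n < 0:
        raise ValueError("target_n must be >= 0")
    rng = np.random.default_rng(seed)
    radii = rng.choice(np.asarray(mixture.radii), size=target_n, p=mixture.weights)
    phi_requested = math.pi * float((radii**2).sum()) / box_side**2
    if phi_requested >= 0.7:
        raise ValueError(
            f"requested packing phi = {phi_requested:.2f} >= 0.7: random "
            "sequential insertion is infeasible; lower phi or use a lattice start"
        )
    # place large disks first: RSA succeeds far more often that way
    radii = np.sort(radii)[::-1]
    centers = np.empty((target_n, 2))
    for i in range(target_n):
        placed = False
        for _ in range(max_attempts_per_disk):
            pos = rng.uniform(0.0, box_side, size=2)
            d = centers[:i] - pos
            d -= box_side * np.round(d / box_side)
            if ((d**2).sum(axis=1) >= (radii[:i] + radii[i]) ** 2).all():
                centers[i] = pos
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"failed to insert disk {i + 1}/{target_n}: lower phi or use a "
                "lattice start"
            )
    return DiskConfiguration(box_side, centers, radii)


def run_metropolis(
    config: DiskConfiguration, settings: McSettings
) -> list[DiskConfiguration]:
    """Sample hard-disk configurations by single-disk Metropolis moves.

    Displacement moves that create an overlap are rejected, which realises
    the hard-disk Boltzmann measure (every non-overlapping configuration is
    equally likely); detailed balance holds because the move proposal is
    symmetric.  Returns decorrelated snapshots taken every
    ``sample_interval`` sweeps after ``n_equilibration`` sweeps.
    """
    L = config.box_side
    centers = config.centers.copy()
    radii = config.radii.copy()
    n = len(radii)
    if n == 0:
        return [DiskConfiguration(L, centers.copy(), radii.copy())]
    if config.has_overlap():
        raise ValueError("starting configuration contains overlaps")
    rng = np.random.default_rng(settings.seed)
    step = settings.max_step if settings.max_step is not None else min(
        L / 10.0, float(radii.mean())
    )
    tune = settings.max_step is None
    sum_r = radii[:, None] + radii[None, :]

    def sweep(step: float) -> int:
        accepted = 0
        order = rng.integers(0, n, size=n)
        moves = rng.uniform(-step, step, size=(n, 2))
        for k in range(n):
            i = order[k]
            new = (centers[i] + moves[k]) % L
            d = centers - new
            d -= L * np.round(d / L)
            dist2 = (d**2).sum(axis=1)
            dist2[i] = np.inf
            if (dist2 >= sum_r[i] ** 2).all():
                centers[i] = new
                accepted += 1
        return accepted

    # equilibration, optionally tuning the step toward ~40% acceptance
    block_acc = block_tot = 0
    for s in range(settings.n_equilibration):
        block_acc += sweep(step)
        block_tot += n
        if tune and (s + 1) % 50 == 0:
            rate = block_acc / block_tot
            if rate < 0.3:
                step = max(step * 0.7, 1e-4 * L)
            elif rate > 0.5:
                step = min(step * 1.3, L / 2)
            block_acc = block_tot = 0
    if block_tot:
        logger.debug("equilibration acceptance %.2f, step %.3g", block_acc / block_tot, step)

    samples: list[DiskConfiguration] = []
    acc = tot = 0
    for s in range(settings.n_sweeps):
        acc += sweep(step)
        tot += n
        if (s + 1) % settings.sample_interval == 0:
            samples.append(DiskConfiguration(L, centers.copy(), radii.copy()))
    logger.info(
        "metropolis: %d disks, step %.3g nm, acceptance %.2f, %d samples",
        n, step, acc / tot, len(samples),
    )
    return samples


def widom_insertion_probability(
    samples: Sequence[DiskConfiguration],
    test_radius: float,
    n_trials: int,
    seed: int,
) -> tuple[float, float]:
    """Widom estimate of the insertion probability exp(-mu_ex(R)).

    Throws ``n_trials`` uniformly random ghost disks of radius R into each
    sampled configuration and counts the fraction that overlap no disk
    (minimum image).  Returns (p_hat, stderr) with the standard error taken
    over between-sample means, which respects correlations within a sample.
    """
    if len(samples) == 0:
        raise ValueError("need at least one sample")
    if test_radius < 0:
        raise ValueError("test radius must be >= 0")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    L = samples[0].box_side
    r_max = max((float(s.radii.max()) for s in samples if s.n_disks), default=0.0)
    if test_radius + r_max > L / 2:
        raise ValueError(
            "R + r_max exceeds half the box: minimum-image overlap test invalid"
        )
    rng = np.random.default_rng(seed)
    means = np.empty(len(samples))
    for j, s in enumerate(samples):
        pts = rng.uniform(0.0, L, size=(n_trials, 2))
        if s.n_disks == 0:
            means[j] = 1.0
            continue
        d = pts[:, None, :] - s.centers[None, :, :]
        d -= L * np.round(d / L)
        dist2 = (d**2).sum(axis=-1)
        ok = (dist2 >= (s.radii[None, :] + test_radius) ** 2).all(axis=1)
        means[j] = ok.mean()
    p_hat = float(means.mean())
    stderr = (
        float(means.std(ddof=1) / math.sqrt(len(means))) if len(means) > 1 else 0.0
    )
    return p_hat, stderr


def exact_free_area_one_crowder(
    box_side: float, channel_radius: float, crowder_radius: float
) -> float:
    """Closed-form free area for one crowder in a hard-wall box with a channel.

    The crowder center is confined to the square [r, L-r]^2 and excluded
    from the disk of radius R+r around the centered channel, giving
    (L-2r)^2 - pi*(R+r)^2.  Requires the exclusion disk to fit inside the
    allowed band and the free area to be positive.
    """
    L, R, r = box_side, channel_radius, crowder_radius
    if R < 0 or r < 0:
        raise ValueError("radii must be >= 0")
    if L - 2 * r <= 0:
        raise ValueError("box smaller than the crowder exclusion band")
    if R + r > L / 2 - r:
        raise ValueError("exclusion disk extends beyond the allowed band")
    free = (L - 2 * r) ** 2 - math.pi * (R + r) ** 2
    if free <= 0:
        raise ValueError("no free area: box too small")
    return free


def grid_free_area_one_crowder(
    box_side: float,
    channel_radius: float,
    crowder_radius: float,
    resolution: int = 2000,
) -> float:
    """Midpoint-rule estimate of the same free area, for cross-validation.

    Only the exclusion disk is gridded (the band is exact), so the error is
    set by the disk perimeter times the cell size and converges to the
    closed form as resolution grows.
    """
    L, R, r = box_side, channel_radius, crowder_radius
    rho = R + r
    band_area = (L - 2 * r) ** 2
    if rho == 0.0:
        return band_area
    h = 2 * rho / resolution
    ax = (np.arange(resolution) + 0.5) * h - rho
    x2 = ax**2
    inside = (x2[:, None] + x2[None, :]) < rho**2
    return band_area - float(inside.sum()) * h * h


# --------------------------------------------------------------------------
# File I/O, tables, fixtures
# --------------------------------------------------------------------------


def read_tm_table(path: str | Path) -> TMHelixTable:
    """Read a TM-helix abundance table from headered TSV.

    Columns ``n_tm_helices`` (int) and ``abundance`` (float); lines starting
    with ``#`` are ignored.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"n_tm_helices", "abundance"} - set(df.columns)
    if missing:
        raise ValueError(f"TM table {path} missing columns: {sorted(missing)}")
    return TMHelixTable(
        tuple(int(n) for n in df["n_tm_helices"]),
        tuple(float(a) for a in df["abundance"]),
    )


def mixture_from_config(mapping: Mapping) -> CrowderMixture:
    """Build a mixture from a plain config mapping.

    Accepts either a uniform spec (``radius``) or an explicit mixture
    (``radii`` + ``abundances``), with exactly one of ``concentration`` /
    ``area_fraction``, or a ``tm_table`` path (plus optional
    ``helix_footprint``).
    """
    m = dict(mapping)
    conc = m.pop("concentration", None)
    phi = m.pop("area_fraction", None)
    if (conc is None) == (phi is None):
        raise ValueError(
            "crowder config needs exactly one of concentration / area_fraction"
        )
    if "tm_table" in m:
        table = read_tm_table(m["tm_table"])
        return CrowderMixture.from_tm_table(
            table,
            helix_footprint=m.get("helix_footprint", DEFAULT_HELIX_FOOTPRINT_NM2),
            concentration=conc,
            area_fraction=phi,
        )
    if "radius" in m:
        return CrowderMixture.uniform(
            float(m["radius"]), concentration=conc, area_fraction=phi
        )
    if "radii" in m:
        radii = tuple(float(r) for r in m["radii"])
        weights = tuple(float(w) for w in m.get("abundances", [1.0] * len(radii)))
        if conc is None:
            w = np.asarray(weights) / np.sum(weights)
            conc = concentration_for_fraction(phi, float(w @ np.asarray(radii) ** 2))
        return CrowderMixture(radii, weights, conc)
    raise ValueError("crowder config needs one of: radius, radii, tm_table")


def mixture_to_config(mixture: CrowderMixture) -> dict:
    """Serialise a mixture to a plain mapping (round-trips with the above)."""
    return {
        "radii": list(mixture.radii),
        "abundances": list(mixture.abundances),
        "concentration": mixture.concentration,
    }


def mixture_stats_table(mixture: CrowderMixture) -> pd.DataFrame:
    """One-row summary of the mixture's derived quantities."""
    return pd.DataFrame(
        [
            {
                "concentration_per_nm2": mixture.concentration,
                "area_fraction": mixture.area_fraction,
                "mean_radius_nm": mixture.mean_radius,
                "mean_sq_radius_nm2": mixture.mean_sq_radius,
                "delta2": mixture.delta2,
            }
        ]
    )


def tensions_table(mixture: CrowderMixture) -> pd.DataFrame:
    """Ideal-gas and SPT tensions side by side."""
    rows = []
    for model in ("ideal_gas", "spt"):
        t = tensions_for(mixture, model)
        rows.append(
            {
                "model": model,
                "sigma_kT_per_nm2": t.surface_tension,
                "tau_kT_per_nm": t.line_tension,
            }
        )
    return pd.DataFrame(rows)


def gating_table(
    channel: ChannelGeometry,
    mixture: CrowderMixture,
    applied_tension: float = 0.0,
) -> pd.DataFrame:
    """Crowding gating energies and tension shifts, both ensembles x models.

    Energies are reported rounded to one decimal (kBT) and tension shifts to
    two decimals (kBT/nm^2); full-precision columns are included alongside.
    """
    rows = []
    for ensemble in ("constant_area", "constant_tension"):
        for model in ("ideal_gas", "spt"):
            if ensemble == "constant_area":
                res = gating_energy_constant_area(channel, mixture, model)
            else:
                res = gating_energy_constant_tension(
                    channel, mixture, applied_tension, model
                )
            rows.append(
                {
                    "ensemble": ensemble,
                    "model": model,
                    "crowding_energy_kT": round(res.crowding_energy, 1),
                    "gating_tension_shift_kT_per_nm2": round(
                        res.gating_tension_shift, 2
                    ),
                    "crowding_energy_kT_full": res.crowding_energy,
                    "gating_tension_shift_full": res.gating_tension_shift,
                    "loading_energy_kT": res.loading_energy,
                    "total_kT": res.total,
                }
            )
    return pd.DataFrame(rows)


def popen_curve_table(
    channel: ChannelGeometry,
    mixture: CrowderMixture,
    gating_tension: float,
    tension_min: float = 0.0,
    tension_max: float = 2.0,
    n_points: int = 201,
) -> pd.DataFrame:
    """Open-probability curves vs applied tension: bare, ideal-gas, SPT."""
    sigma = np.linspace(tension_min, tension_max, n_points)
    return pd.DataFrame(
        {
            "sigma_kT_per_nm2": sigma,
            "popen_uncrowded": open_probability(sigma, gating_tension, channel, None),
            "popen_ig": open_probability(
                sigma, gating_tension, channel, mixture, "ideal_gas"
            ),
            "popen_spt": open_probability(
                sigma, gating_tension, channel, mixture, "spt"
            ),
        }
    )


def generate_fixture(
    kind: str,
    outdir: str | Path,
    seed: int = 0,
    *,
    area_fraction: float = 0.5,
    radius: float = 1.0,
    n_species: int = 30,
) -> dict[str, Path]:
    """Write seeded synthetic crowder descriptions to disk.

    ``uniform``: a single-species config mapping (YAML).
    ``two-species``: a two-radius mixture config (YAML).
    ``tm-distribution``: a TM-helix abundance TSV whose counts follow a
    geometric-like decay over 1..n_species helices (most proteins have few
    TM helices, abundances spanning about an order of magnitude), with
    seeded lognormal abundance noise.  Returns {name: path}.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    written: dict[str, Path] = {}
    if kind == "uniform":
        cfg = {"radius": radius, "area_fraction": area_fraction}
        path = outdir / "crowders_uniform.yaml"
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))
        written["config"] = path
    elif kind == "two-species":
        cfg = {
            "radii": [radius, 2.0 * radius],
            "abundances": [0.7, 0.3],
            "area_fraction": area_fraction,
        }
        path = outdir / "crowders_two_species.yaml"
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))
        written["config"] = path
    elif kind == "tm-distribution":
        n = np.arange(1, n_species + 1)
        base = 0.75 ** (n - 1)  # geometric decay: few-helix proteins dominate
        noise = np.exp(rng.normal(0.0, 0.4, size=n_species))
        weights = base * noise
        lines = ["# synthetic TM-helix abundance table", "n_tm_helices\tabundance"]
        lines += [f"{int(k)}\t{w:.6g}" for k, w in zip(n, weights)]
        path = outdir / "tm_distribution.tsv"
        path.write_text("\n".join(lines) + "\n")
        written["tm_table"] = path
        cfg = {"tm_table": str(path), "area_fraction": area_fraction}
        cfg_path = outdir / "crowders_tm.yaml"
        cfg_path.write_text(yaml.safe_dump(cfg, sort_keys=False))
        written["config"] = cfg_path
    else:
        raise ValueError(
            f"unknown fixture kind {kind!r}; use uniform, two-species or "
            "tm-distribution"
        )
    meta = {"kind": kind, "seed": seed, "area_fraction": area_fraction}
    meta_path = outdir / f"fixture_{kind.replace('-', '_')}_meta.json"
    meta_path.write_text(json.dumps(meta, indent=2) + "\n")
    written["metadata"] = meta_path
    return written
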