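"""Per-window stomatal summary statistics: SD, r̄_E, and the Clark–Evans SAI.

Stomatal density (SD) is the count of stomata per mm² of lamina. Under
complete spatial randomness (CSR, a homogeneous Poisson process) at density
ρ the expected nearest-neighbor distance is r̄_E = 1 / (2 √ρ). The stomatal
aggregation index compares the observed mean nearest-neighbor distance to
that expectation,

    SAI = MNND / r̄_E = 2 · MNND · √ρ,

and is dimensionless: SAI < 1 indicates aggregation, SAI = 1 spatial
randomness, SAI > 1 regular (overdispersed) arrangement. The asymptotic
maximum, attained by hexagonal packing, is 2·√(2/√3) ≈ 2.1491.

Unit regime: coordinates and MNND in μm, SD reported in mm⁻². The single
μm²→mm² conversion constant lives in this module; it is also the origin of
the log–log intercept anchor ln(10⁶/4) ≈ 12.43 used in the scaling analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from scipy.stats import norm

from .geometry import PointPattern, nearest_neighbor_distances

#: μm² per mm²; the only place the unit conversion appears.
UM2_PER_MM2 = 1.0e6

#: Asymptotic maximum of the aggregation index (hexagonal lattice).
SAI_MAX = 2.0 * math.sqrt(2.0 / math.sqrt(3.0))


@dataclass(frozen=True)
class WindowStats:
    """Summary statistics for one observation window.

    Attributes
    ----------
    n : int
        Stomata counted in the window.
    sd : float
        Stomatal density, mm⁻².
    mnnd : float
        Mean nearest-neighbor distance, μm.
    r_e : float
        Expected nearest-neighbor distance under CSR at density ``sd``, μm.
    sai : float
        Aggregation index, MNND / r̄_E (dimensionless).
    dispersion : str
        Classification of ``sai``: "aggregated" (< 1), "random" (= 1),
        or "regular" (> 1).
    label : object, optional
        Section metadata carried through from the pattern.
    """

    n: int
    sd: float
    mnnd: float
    r_e: float
    sai: float
    dispersion: str
    label: Optional[object] = None


def stomatal_density(pattern: PointPattern) -> float:
    """Stomatal density of a pattern in mm⁻² (count / window area).

    An empty pattern has density zero. For the default 1200 x 900 μm
    window the area is 1.08 mm², so e.g. 270 stomata give 250 mm⁻².
    """
    return pattern.n / pattern.window.area_mm2


def expected_nn_distance_csr(sd_mm2: float) -> float:
    """Expected nearest-neighbor distance (μm) under CSR at density ``sd_mm2``.

    Implements r̄_E = 1 / (2 √ρ) with ρ the density in μm⁻²
    (ρ = sd / 10⁶); equivalently, density = 1 / (4 r̄_E²).
    """
    if sd_mm2 <= 0:
        raise ValueError(f"density must be positive, got {sd_mm2}")
    return 1.0 / (2.0 * math.sqrt(sd_mm2 / UM2_PER_MM2))


def classify_dispersion(sai: float) -> str:
    """Classify an aggregation index: aggregated (<1), random (=1), regular (>1)."""
    if sai < 0:
        raise ValueError(f"SAI must be non-negative, got {sai}")
    if sai < 1.0:
        return "aggregated"
    if sai == 1.0:
        return "random"
    return "regular"


def aggregation_index(mnnd_um: float, sd_mm2: float) -> float:
    """Clark–Evans aggregation index SAI = MNND / r̄_E = 2·MNND·√ρ.

    ``mnnd_um`` in μm, ``sd_mm2`` in mm⁻². The two algebraic forms are the
    same expression; the ratio form is evaluated here. Dimensionless (any
    coherent rescaling of lengths leaves it unchanged).
    """
    if mnnd_um < 0:
        raise ValueError(f"MNND must be non-negative, got {mnnd_um}")
    return mnnd_um / expected_nn_distance_csr(sd_mm2)


def window_stats(pattern: PointPattern, metric: str = "euclidean") -> WindowStats:
    """Assemble the per-window record: n, SD, MNND, r̄_E, SAI.

    The SAI is computed from the same SD and MNND reported in the record.
    Requires n >= 2 (MNND undefined otherwise).
    """
    if pattern.n < 2:
        wid = f" (window {pattern.label})" if pattern.label is not None else ""
        raise ValueError(
            f"window statistics need at least 2 points, got {pattern.n}{wid}"
        )
    sd = stomatal_density(pattern)
    mnnd = float(nearest_neighbor_distances(pattern, metric=metric).mean())
    r_e = expected_nn_distance_csr(sd)
    sai = mnnd / r_e
    return WindowStats(
        n=pattern.n, sd=sd, mnnd=mnnd, r_e=r_e, sai=sai,
        dispersion=classify_dispersion(sai), label=pattern.label,
    )


def clark_evans_test(pattern: PointPattern, metric: str = "euclidean"):
    """Clark–Evans z-test of the CSR null (SAI = 1) for one window.

    Optional extra, not part of the default reporting path: the pipeline
    reports SAI descriptively relative to 1. Uses the classical normal
    approximation with SE(MNND) = 0.26136 / √(n ρ) (ρ in μm⁻²), no edge
    correction.

    Returns
    -------
    (z, p) : tuple of float
        z statistic and two-sided p-value.
    """
    st = window_stats(pattern, metric=metric)
    rho = st.sd / UM2_PER_MM2
    se = 0.26136 / math.sqrt(st.n * rho)
    z = (st.mnnd - st.r_e) / se
    p = 2.0 * float(norm.sf(abs(z)))
    return z, p
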