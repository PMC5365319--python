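"""Plasmodesma and cell-wall interface geometry.

A plasmodesma (PD) is a membrane-lined nanochannel through the plant cell
wall.  Its core is the desmotubule, a strand of appressed endoplasmic
reticulum; transport takes place in the annular cytoplasmic sleeve between
the desmotubule and the channel wall.  Two PD classes occur in the
Arabidopsis root unloading zone:

* **simple** PD — a straight channel of constant cross-section; and
* **funnel** PD — wide at the sieve-element (PSE) mouth, tapering to a
  conventional narrow neck at the pericycle (PPP) side.

Axial position ``x`` is measured in nm from the PSE-side wall face,
increasing toward the PPP.  The funnel taper is modelled as a linear
interpolation of the outer wall radius between the mouth and the neck,
the minimal assumption consistent with conical TEM profiles.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_NECK_FRACTION",
    "PDGeometry",
    "PDCensus",
    "InterfaceCounts",
    "radius_profile",
    "interface_counts",
    "INTERFACES",
]

#: Fraction of the wall length occupied by the desmotubule-obstructed neck in
#: the ``neck_only`` placement mode.  Calibrated so that the favourable
#: desmotubule extreme of the base mixed PD population requires 0.05 MPa to
#: carry the full unloading flow (see docs/methods.md).
DEFAULT_NECK_FRACTION = 0.00530

#: Wall interfaces of a protophloem sieve element, in reporting order:
#: phloem-pole pericycle, companion cell, metaphloem sieve element.
INTERFACES = ("PSE-PPP", "PSE-CC", "PSE-MSE")


@dataclass(frozen=True)
class PDGeometry:
    """Geometry of a single plasmodesma.

    Parameters
    ----------
    kind:
        ``"simple"`` (constant cross-section) or ``"funnel"`` (linear taper
        from a wide PSE-side mouth to a narrow PPP-side neck).
    desmotubule_diameter_nm:
        Diameter of the central desmotubule.
    sleeve_width_nm:
        Radial width of the cytoplasmic sleeve at the neck, i.e. the gap
        between desmotubule and wall.
    wall_length_nm:
        Axial channel length (= cell wall thickness).
    mouth_diameter_nm:
        Funnel only: outer channel diameter at the PSE entrance.
    desmotubule_mode:
        Funnel only.  ``"full_span"``: the desmotubule runs the entire wall
        length, so every cross-section is annular.  ``"neck_only"``: the
        desmotubule obstructs only the final ``neck_fraction`` of the length;
        the wide region is an open cone.  These are the two placement
        extremes bracketing the funnel's hydraulic resistance.
    neck_fraction:
        Funnel, ``neck_only`` mode: fraction of ``wall_length_nm`` occupied
        by the obstructed neck, in (0, 1].
    """

    kind: Literal["simple", "funnel"] = "simple"
    desmotubule_diameter_nm: float = 15.0
    sleeve_width_nm: float = 2.8
    wall_length_nm: float = 500.0
    mouth_diameter_nm: float | None = None
    desmotubule_mode: Literal["full_span", "neck_only"] = "full_span"
    neck_fraction: float = DEFAULT_NECK_FRACTION

    def __post_init__(self) -> None:
        if self.kind not in ("simple", "funnel"):
            raise ValueError(f"kind must be 'simple' or 'funnel', got {self.kind!r}")
        for name in ("desmotubule_diameter_nm", "sleeve_width_nm", "wall_length_nm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.kind == "funnel":
            if self.mouth_diameter_nm is None:
                raise ValueError("mouth_diameter_nm is required for funnel PDs")
            if self.mouth_diameter_nm < self.neck_outer_diameter_nm:
                raise ValueError(
                    "mouth_diameter_nm must be >= neck outer diameter "
                    f"({self.neck_outer_diameter_nm:g} nm)"
                )
            if self.desmotubule_mode not in ("full_span", "neck_only"):
                raise ValueError(
                    "desmotubule_mode must be 'full_span' or 'neck_only', "
                    f"got {self.desmotubule_mode!r}"
                )
            if not 0 < self.neck_fraction <= 1:
                raise ValueError("neck_fraction must lie in (0, 1]")
        elif self.mouth_diameter_nm is not None:
            raise ValueError("mouth_diameter_nm applies only to funnel PDs")

    # -- derived radii ----------------------------------------------------

    @property
    def desmotubule_radius_nm(self) -> float:
        return self.desmotubule_diameter_nm / 2.0

    @property
    def neck_outer_radius_nm(self) -> float:
        """Outer wall radius at the neck (= simple-PD outer radius)."""
        return self.desmotubule_radius_nm + self.sleeve_width_nm

    @property
    def neck_outer_diameter_nm(self) -> float:
        return 2.0 * self.neck_outer_radius_nm

    @property
    def mouth_radius_nm(self) -> float:
        if self.kind == "simple":
            return self.neck_outer_radius_nm
        assert self.mouth_diameter_nm is not None
        return self.mouth_diameter_nm / 2.0

    # -- constructors ------------------------------------------------------

    @classmethod
    def simple(
        cls,
        desmotubule_diameter_nm: float = 15.0,
        sleeve_width_nm: float = 2.8,
        wall_length_nm: float = 500.0,
    ) -> "PDGeometry":
        return cls(
            kind="simple",
            desmotubule_diameter_nm=desmotubule_diameter_nm,
            sleeve_width_nm=sleeve_width_nm,
            wall_length_nm=wall_length_nm,
        )

    @classmethod
    def funnel(
        cls,
        mouth_diameter_nm: float = 150.0,
        desmotubule_diameter_nm: float = 15.0,
        sleeve_width_nm: float = 2.8,
        wall_length_nm: float = 500.0,
        desmotubule_mode: Literal["full_span", "neck_only"] = "full_span",
        neck_fraction: float = DEFAULT_NECK_FRACTION,
    ) -> "PDGeometry":
        return cls(
            kind="funnel",
            desmotubule_diameter_nm=desmotubule_diameter_nm,
            sleeve_width_nm=sleeve_width_nm,
            wall_length_nm=wall_length_nm,
            mouth_diameter_nm=mouth_diameter_nm,
            desmotubule_mode=desmotubule_mode,
            neck_fraction=neck_fraction,
        )


def radius_profile(geom: PDGeometry, x_nm):
    """Outer wall radius (nm) at axial position ``x_nm``.

    ``x_nm`` may be a scalar or array; positions must lie in
    ``[0, wall_length_nm]`` (x = 0 at the PSE-side mouth).  Simple PDs have a
    constant radius; funnels taper linearly from mouth to neck.
    """
    x = np.asarray(x_nm, dtype=float)
    if np.any(x < 0) or np.any(x > geom.wall_length_nm):
        raise ValueError(
            f"axial position outside [0, {geom.wall_length_nm:g}] nm"
        )
    r_neck = geom.neck_outer_radius_nm
    if geom.kind == "simple":
        out = np.full_like(x, r_neck)
    else:
        r_mouth = geom.mouth_radius_nm
        out = r_mouth + (r_neck - r_mouth) * x / geom.wall_length_nm
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# PD census
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PDCensus:
    """Plasmodesma census of one protophloem unloading domain.

    ``total_mean``/``total_sd`` describe the total PD count per unloading
    domain across ``n_domains`` reconstructed domains; ``fractions`` is the
    relative distribution across the (PSE–PPP, PSE–CC, PSE–MSE) wall
    interfaces and must sum to 1 within 0.005.
    """

    total_mean: float = 527.0
    total_sd: float = 58.0
    n_domains: int = 4
    fractions: tuple[float, float, float] = (0.453, 0.408, 0.139)

    def __post_init__(self) -> None:
        if not self.total_mean > 0:
            raise ValueError("total_mean must be strictly positive")
        if self.total_sd < 0:
            raise ValueError("total_sd must be non-negative")
        if self.n_domains < 1:
            raise ValueError("n_domains must be >= 1")
        if len(self.fractions) != 3 or any(f < 0 for f in self.fractions):
            raise ValueError("fractions must be three non-negative values")
        if abs(sum(self.fractions) - 1.0) > 0.005:
            raise ValueError(
                f"fractions must sum to 1 within 0.005 (got {sum(self.fractions):.4f})"
            )


@dataclass(frozen=True)
class InterfaceCounts:
    """PD counts per wall interface derived from a census.

    ``ppp_nearest_ten`` restates the PSE–PPP count rounded to the nearest
    ten — the resolution at which that count is conventionally quoted.
    """

    ppp: int
    cc: int
    mse: int
    ppp_nearest_ten: int = field(default=0)

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.ppp, self.cc, self.mse)

    def to_frame(self, census: PDCensus) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "interface": list(INTERFACES),
                "fraction": list(census.fractions),
                "count": list(self.as_tuple()),
            }
        )


def interface_counts(census: PDCensus) -> InterfaceCounts:
    """Allocate the census total across the three wall interfaces.

    Each interface count is ``round(total_mean * fraction)`` to the nearest
    integer; the PSE–PPP count is additionally reported to the nearest ten.
    The three counts always sum to within 1 of the rounded total.
    """
    raw = [census.total_mean * f for f in census.fractions]
    counts = [int(round(v)) for v in raw]
    return InterfaceCounts(
        ppp=counts[0],
        cc=counts[1],
        mse=counts[2],
        ppp_nearest_ten=int(round(raw[0] / 10.0) * 10),
    )


def census_to_csv(census: PDCensus, path=None) -> str:
    """Write ``interface,fraction,count`` CSV; return the CSV text."""
    frame = interface_counts(census).to_frame(census)
    buf = io.StringIO()
    frame.to_csv(buf, index=False)
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def census_from_csv(path, total_mean: float | None = None) -> PDCensus:
    """Read a census CSV (``interface,fraction[,count]``).

    ``total_mean`` overrides the total; otherwise the count column sum is
    used.
    """
    frame = pd.read_csv(path)
    frame = frame.set_index("interface").reindex(list(INTERFACES))
    if frame["fraction"].isna().any():
        raise ValueError(f"census CSV must contain rows for {INTERFACES}")
    total = total_mean
    if total is None:
        if "count" not in frame:
            raise ValueError("census CSV without counts requires total_mean")
        total = float(frame["count"].sum())
    fr = frame["fraction"].to_numpy(dtype=float)
    return PDCensus(total_mean=float(total), total_sd=0.0, n_domains=1,
                    fractions=(fr[0], fr[1], fr[2]))
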