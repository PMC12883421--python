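"""Class-conditional generator profiles for the three MPN subtypes.

A :class:`ClassProfile` bundles the parameters that drive the synthetic
bone-marrow ROI generator: the marrow cellularity distribution of the
diagnostic class, the size/shape distribution of megakaryocyte nuclei,
the typical small (erythroid/myeloid) nucleus size, and the adipocyte
size range.  Cellularity means and standard deviations of the default
profiles are the published per-class cohort values; megakaryocyte and
adipocyte parameters are package defaults chosen to be histologically
plausible (documented in ``docs/methods.md``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "CLASS_ORDER",
    "ClassProfile",
    "make_default_profiles",
    "blend_profiles",
]

#: Fixed order of the three diagnostic classes everywhere in the package
#: (score vectors, tie-breaking, report columns).
CLASS_ORDER: tuple[str, str, str] = ("pre-PMF", "PV", "ET")


@dataclass(frozen=True)
class ClassProfile:
    """Parameters of one diagnostic class for the synthetic generator.

    Parameters
    ----------
    label
        Diagnosis label (``pre-PMF``, ``PV``, ``ET`` or a blend label).
    cellularity_mean, cellularity_sd
        Mean and SD of marrow cellularity (unitless fraction in (0, 1)).
    mk_fraction_mean, mk_fraction_sd
        Expected fraction of total nuclear area contributed by
        megakaryocyte nuclei.
    mk_area_mean_um2, mk_area_sd_um2
        Megakaryocyte nuclear area distribution, µm².
    small_cell_area_mean_um2
        Typical erythroid/myeloid nucleus area, µm².
    mk_lobulation
        Integer ≥ 1 controlling the number of nuclear lobes rendered for
        megakaryocytes (drives eccentricity and maximum caliper).
    adipocyte_radius_um_range
        (min, max) adipocyte radius in µm.
    """

    label: str
    cellularity_mean: float
    cellularity_sd: float
    mk_fraction_mean: float
    mk_fraction_sd: float
    mk_area_mean_um2: float
    mk_area_sd_um2: float
    small_cell_area_mean_um2: float
    mk_lobulation: int
    adipocyte_radius_um_range: tuple[float, float]

    def __post_init__(self) -> None:
        if not 0.0 < self.cellularity_mean < 1.0:
            raise ValueError("cellularity_mean must lie in (0, 1)")
        for name in ("cellularity_sd", "mk_fraction_sd", "mk_area_sd_um2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.mk_fraction_mean <= 1.0:
            raise ValueError("mk_fraction_mean must lie in [0, 1]")
        if self.mk_area_mean_um2 <= self.small_cell_area_mean_um2:
            raise ValueError(
                "megakaryocyte nuclei must be larger than small-cell nuclei"
            )
        if self.mk_lobulation < 1:
            raise ValueError("mk_lobulation must be an integer >= 1")
        lo, hi = self.adipocyte_radius_um_range
        if not (0 < lo <= hi):
            raise ValueError("adipocyte_radius_um_range must be 0 < lo <= hi")


def make_default_profiles() -> tuple[ClassProfile, ClassProfile, ClassProfile]:
    """Default profiles for pre-PMF, PV and ET (in :data:`CLASS_ORDER`).

    Cellularity parameters are the published per-class cohort mean ± SD
    (0.55 ± 0.12 pre-PMF, 0.67 ± 0.13 PV, 0.65 ± 0.14 ET).  Megakaryocyte
    morphology defaults encode the qualitative histology of each subtype:
    pre-PMF nuclei bulbous/hypolobulated, PV nuclei pleomorphic, ET nuclei
    large and hyperlobulated ("staghorn").
    """
    pre_pmf = ClassProfile(
        label="pre-PMF",
        cellularity_mean=0.55,
        cellularity_sd=0.12,
        mk_fraction_mean=0.30,
        mk_fraction_sd=0.06,
        mk_area_mean_um2=240.0,
        mk_area_sd_um2=50.0,
        small_cell_area_mean_um2=38.0,
        mk_lobulation=2,
        adipocyte_radius_um_range=(12.0, 30.0),
    )
    pv = ClassProfile(
        label="PV",
        cellularity_mean=0.67,
        cellularity_sd=0.13,
        mk_fraction_mean=0.22,
        mk_fraction_sd=0.05,
        mk_area_mean_um2=220.0,
        mk_area_sd_um2=45.0,
        small_cell_area_mean_um2=38.0,
        mk_lobulation=3,
        adipocyte_radius_um_range=(12.0, 30.0),
    )
    et = ClassProfile(
        label="ET",
        cellularity_mean=0.65,
        cellularity_sd=0.14,
        mk_fraction_mean=0.28,
        mk_fraction_sd=0.05,
        mk_area_mean_um2=280.0,
        mk_area_sd_um2=60.0,
        small_cell_area_mean_um2=38.0,
        mk_lobulation=4,
        adipocyte_radius_um_range=(12.0, 30.0),
    )
    return pre_pmf, pv, et


def blend_profiles(a: ClassProfile, b: ClassProfile, mix: float) -> ClassProfile:
    """Convex combination of two profiles: ``(1-mix)*a + mix*b``.

    ``mix=0`` returns a profile identical to ``a`` and ``mix=1`` one
    identical to ``b`` (exactly, field by field).  Used to emulate
    MPN-NOS cases with overlapping clinicopathological features.
    """
    if not 0.0 <= mix <= 1.0:
        raise ValueError("mix must lie in [0, 1]")
    if mix == 0.0:
        return replace(a)
    if mix == 1.0:
        return replace(b)

    def lerp(x: float, y: float) -> float:
        return (1.0 - mix) * x + mix * y

    return ClassProfile(
        label=f"{a.label}|{b.label}({mix:g})",
        cellularity_mean=lerp(a.cellularity_mean, b.cellularity_mean),
        cellularity_sd=lerp(a.cellularity_sd, b.cellularity_sd),
        mk_fraction_mean=lerp(a.mk_fraction_mean, b.mk_fraction_mean),
        mk_fraction_sd=lerp(a.mk_fraction_sd, b.mk_fraction_sd),
        mk_area_mean_um2=lerp(a.mk_area_mean_um2, b.mk_area_mean_um2),
        mk_area_sd_um2=lerp(a.mk_area_sd_um2, b.mk_area_sd_um2),
        small_cell_area_mean_um2=lerp(
            a.small_cell_area_mean_um2, b.small_cell_area_mean_um2
        ),
        mk_lobulation=max(1, round(lerp(a.mk_lobulation, b.mk_lobulation))),
        adipocyte_radius_um_range=(
            lerp(a.adipocyte_radius_um_range[0], b.adipocyte_radius_um_range[0]),
            lerp(a.adipocyte_radius_um_range[1], b.adipocyte_radius_um_range[1]),
        ),
    )
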