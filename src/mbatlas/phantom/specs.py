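"""Parameter objects for the synthetic-brain generators.

The phantoms emulate the inputs the imaging pipeline consumes: a whole-brain
reference (synaptic-density) channel with lobe-shaped neuropils, compartment
tilings with optionally dimmed borders, compartmentalized tubular arbors with
presynaptically enriched terminal boutons, nucleus fields with a controllable
size distribution and touching fraction, specimen-specific affine + smooth
nonlinear deformations, and Poisson–Gaussian imaging noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["NucleiSpec", "NoiseSpec", "DeformationSpec", "PhantomSpec"]

#: compartment borders carrying reduced synaptic density in the reference
#: channel (synthetic stand-ins for the four bordering gaps seen in aligned
#: arbor data; configurable).
DEFAULT_DIMMED_BORDERS = (("g1", "g2"), ("g3", "g4"), ("b1", "b2"), ("a1", "a2"))


@dataclass(frozen=True)
class NucleiSpec:
    """Blob-like nuclei with a narrow size distribution.

    Diameters are drawn from a normal truncated at ±0.8 SD so every generated
    nucleus sits safely inside a mean ± 2 SD size gate even after the small
    apparent-size bias of intensity thresholding.  ``touching_fraction`` of
    the nuclei are placed in surface-touching pairs that merge under a low
    intensity threshold but separate at a high one.
    """

    n: int = 50
    mean_diameter_um: float = 4.5
    sd_um: float = 0.35
    touching_fraction: float = 0.0
    amplitude_range: tuple[float, float] = (0.95, 1.0)
    blur_sigma_vox: float = 0.5   # membrane-shell smoothing only
    bleed_coefficient: float = 0.3   # membrane bleed-through into the nuclear channel

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if not 0 <= self.touching_fraction <= 1:
            raise ValueError("touching_fraction must be in [0, 1]")


@dataclass(frozen=True)
class NoiseSpec:
    """Poisson shot noise on scaled intensities + additive Gaussian read noise."""

    gaussian_sd: float = 0.01
    poisson_gain: float | None = 200.0  # photons per intensity unit; None disables

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0:
            raise ValueError("gaussian_sd must be >= 0")


@dataclass(frozen=True)
class DeformationSpec:
    """Ranges for random specimen deformations (affine + smooth field)."""

    rotation_max_deg: float = 10.0
    scale_max: float = 0.10
    translation_max_vox: float = 5.0
    field_amplitude_vox: float = 2.0
    field_sigma_vox: float = 8.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the synthetic standard brain (desk scale by default).

    The default grid is 128×128×96 (x, y, z) at 0.76 µm isotropic — twice the
    0.38 µm working resolution of the real standard brain — so that every
    generator and test runs in seconds.
    """

    shape: tuple[int, int, int] = (96, 128, 128)   # (z, y, x)
    spacing_um: float = 0.76
    tube_radius_vox: float = 7.0
    pedc_length_vox: int = 6
    border_dip_factor: float = 0.4
    border_halfwidth_vox: int = 2
    dimmed_borders: tuple[tuple[str, str], ...] = DEFAULT_DIMMED_BORDERS
    reference_blur_sigma: float = 0.8
    nuclei: NucleiSpec = field(default_factory=NucleiSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    deformation: DeformationSpec = field(default_factory=DeformationSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing_um <= 0:
            raise ValueError("spacing must be positive")
        if not 0 < self.border_dip_factor <= 1:
            raise ValueError("border_dip_factor must be in (0, 1]")
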