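"""Conversions between laboratory units and the model's normalized biovolume units.

Laboratory measurements arrive as particle abundances (particles mL^-1) and an
adsorption rate (mL h^-1).  The model works in normalized biovolume: bacterial
abundance is divided by the half-saturation abundance ``N_H`` (1.00e7
particles mL^-1), so the half-saturation density becomes exactly 1; phage
abundance is additionally scaled by the phage-to-bacterium biovolume ratio
``c`` (3.14e-4).  The mass-action adsorption rate changes units accordingly:
``i_norm = i * N_H / c`` turns mL h^-1 into a normalized h^-1 rate.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "RawQuantities",
    "normalize_bacteria",
    "normalize_phage",
    "normalize_adsorption",
    "denormalize_abundance",
]


@dataclass(frozen=True)
class RawQuantities:
    """Laboratory-scale reference quantities behind the normalization.

    Attributes
    ----------
    half_saturation_abundance : float
        Bacterial half-saturation abundance N_H [particles mL^-1].
    phage_to_bacteria_volume_ratio : float
        Biovolume of one phage relative to one bacterium (dimensionless).
    """

    half_saturation_abundance: float = 1.00e7
    phage_to_bacteria_volume_ratio: float = 3.14e-4

    def __post_init__(self) -> None:
        if self.half_saturation_abundance <= 0:
            raise ValueError("half-saturation abundance must be positive")
        if self.phage_to_bacteria_volume_ratio <= 0:
            raise ValueError("phage/bacteria volume ratio must be positive")


def normalize_bacteria(abundance: float, raw: RawQuantities = RawQuantities()) -> float:
    """Bacterial abundance [particles mL^-1] -> normalized density."""
    if abundance < 0:
        raise ValueError("abundance must be non-negative")
    return abundance / raw.half_saturation_abundance


def normalize_phage(abundance: float, raw: RawQuantities = RawQuantities()) -> float:
    """Phage abundance [particles mL^-1] -> normalized density.

    Phage biovolume is a factor ``c`` smaller per particle, so the abundance
    is scaled by ``c`` before dividing by the half-saturation abundance.
    """
    if abundance < 0:
        raise ValueError("abundance must be non-negative")
    return abundance * raw.phage_to_bacteria_volume_ratio / raw.half_saturation_abundance


def normalize_adsorption(rate: float, raw: RawQuantities = RawQuantities()) -> float:
    """Adsorption rate [mL h^-1] -> normalized rate [h^-1].

    The mass-action term ``i * B * P`` must keep its units when ``B`` and
    ``P`` become normalized biovolumes, which requires
    ``i_norm = i * N_H / c``.  With the default constants,
    1.64e-10 mL h^-1 maps to ~5.22 h^-1.
    """
    if rate < 0:
        raise ValueError("adsorption rate must be non-negative")
    return rate * raw.half_saturation_abundance / raw.phage_to_bacteria_volume_ratio


def denormalize_abundance(density: float, compartment: str,
                          raw: RawQuantities = RawQuantities()) -> float:
    """Normalized density -> abundance [particles mL^-1].

    Exact inverse of :func:`normalize_bacteria` / :func:`normalize_phage`;
    ``compartment`` is ``"bacteria"`` (also for infected bacteria and
    nutrient, which share the bacterial normalization) or ``"phage"``.
    """
    if density < 0:
        raise ValueError("density must be non-negative")
    if compartment == "bacteria":
        return density * raw.half_saturation_abundance
    if compartment == "phage":
        return density * raw.half_saturation_abundance / raw.phage_to_bacteria_volume_ratio
    raise ValueError(f"unknown compartment {compartment!r}; expected 'bacteria' or 'phage'")
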