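"""Ready-made configurations of the two model canopies.

Canopy A is rice-like: broad disc leaves plus stalk segments (ground
measurements from a paddy field). Canopy B is forest-like: needle leaves
plus branch segments. Stalk and branch lengths are shortened so each element
acts as a finite scatterer filling the canopy space. All components share
the same volume density (8e-5 cm^-3 by default) and the canonical
orientations of the crown-shape study: plate-like leaves horizontal, needle
leaves horizontal with random in-plane orientation, stalks and branches
vertical.
"""

from __future__ import annotations

from .dielectric import vegetation_permittivity
from .scatterer_models import ScattererSpec

__all__ = ["canopy_species", "CANOPY_PARAMETERS"]

#: Component geometry (cm) and volumetric moisture of the two canopies.
CANOPY_PARAMETERS = {
    "A": {
        "leaf": dict(shape="disc", radius=3.0, thickness_or_length=0.02,
                     moisture=0.85, approximation="physical_optics",
                     axis=(0.0, 0.0, 1.0), randomize_azimuth=False),
        "stalk": dict(shape="cylinder", radius=1.25, thickness_or_length=10.0,
                      moisture=0.85, approximation="infinite_cylinder",
                      axis=(0.0, 0.0, 1.0), randomize_azimuth=False),
    },
    "B": {
        "leaf": dict(shape="cylinder", radius=0.3, thickness_or_length=4.0,
                     moisture=0.6, approximation="rayleigh_gans",
                     axis=(1.0, 0.0, 0.0), randomize_azimuth=True),
        "branch": dict(shape="cylinder", radius=0.2, thickness_or_length=30.0,
                       moisture=0.6, approximation="infinite_cylinder",
                       axis=(0.0, 0.0, 1.0), randomize_azimuth=False),
    },
}


def canopy_species(canopy: str, frequency_ghz: float) -> list[ScattererSpec]:
    """Scatterer specs of canopy ``"A"`` or ``"B"`` at a given frequency.

    The component permittivities are evaluated from the tabulated moisture
    values with the vegetation dielectric model at the requested frequency.
    """
    try:
        params = CANOPY_PARAMETERS[canopy.upper()]
    except KeyError:
        raise ValueError(f"unknown canopy {canopy!r}; use 'A' or 'B'") from None
    specs = []
    for name, p in params.items():
        q = dict(p)
        eps = vegetation_permittivity(q.pop("moisture"), frequency_ghz)
        specs.append(ScattererSpec(permittivity=eps, name=name, **q))
    return specs
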