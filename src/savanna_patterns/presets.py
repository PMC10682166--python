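"""Named parameter presets for reproducing the reference scenarios.

Each preset bundles a model variant, demographic parameters, Gaussian
kernel widths and a grid.  Two length conventions coexist:

* *simulation presets* put the kernel widths directly on the box
  ``[-pi, pi]`` (the fire-spread width 0.01 etc. are then tiny relative
  to the domain, giving many-bump patterns);
* *continuation presets* interpret the widths as fractions of a
  unit-length periodic domain ``[-1/2, 1/2]``, which places the critical
  wavenumber at integer modes 2-3 and produces the coarse two- and
  three-bump branches.  By scale invariance this is identical to a
  ``[-pi, pi]`` box with all widths multiplied by ``2 pi``.

The sapling seed-dispersal width (``JT``) has no canonical value and
defaults to the forest one.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

from .grids import SpatialGrid
from .kernels import Kernel, make_gaussian
from .nonspatial import ModelParams, default_params

__all__ = ["Preset", "PRESETS", "load_preset", "gaussian_kernels"]


def gaussian_kernels(
    sigma_w: float,
    sigma_f: float,
    sigma_r: float | None = None,
    sigma_t: float | None = None,
    dim: int = 1,
) -> dict[str, Kernel]:
    """Kernel dictionary for the standard roles (fire, seeds, resources)."""
    out = {
        "w": make_gaussian(sigma_w, dim),
        "JF": make_gaussian(sigma_f, dim),
        "JT": make_gaussian(sigma_t if sigma_t is not None else sigma_f, dim),
    }
    if sigma_r is not None:
        out["R"] = make_gaussian(sigma_r, dim)
    return out


@dataclass(frozen=True)
class Preset:
    name: str
    description: str
    params: ModelParams
    kernels: dict[str, Kernel] = dc_field(default_factory=dict)
    grid: SpatialGrid | None = None
    extras: dict = dc_field(default_factory=dict)


def _build() -> dict[str, Preset]:
    presets = {}

    presets["table1"] = Preset(
        "table1",
        "Default demographic rates and sigmoid fire responses of the "
        "four-type model.",
        default_params("SL4"),
    )

    presets["fig3"] = Preset(
        "fig3",
        "Grass-forest resource-limited model; kernel widths for the "
        "(alpha, r) Turing-region heatmaps.",
        default_params("RL-GF"),
        gaussian_kernels(sigma_w=0.05, sigma_f=0.1, sigma_r=0.4),
    )

    presets["fig4"] = Preset(
        "fig4",
        "Pattern-forming simulation point: alpha=2.15, r=1 on [-pi, pi].",
        default_params("RL-GF", alpha=2.15, r=1.0),
        gaussian_kernels(sigma_w=0.01, sigma_f=0.1, sigma_r=0.4),
        SpatialGrid(n=256),
        extras={"grid_2d": SpatialGrid(n=128, half_width=0.5 * 3.141592653589793,
                                       dim=2)},
    )

    # continuation presets: unit-length domain, widths as domain fractions
    unit_grid = SpatialGrid(n=256, half_width=0.5)
    presets["fig5-top"] = Preset(
        "fig5-top",
        "Bifurcation slice r=0.84 with sigma_W=0.025, sigma_F=0.1, "
        "sigma_R=0.15 (resource competition more nonlocal than dispersal); "
        "two-bump branch seeded at alpha=4.5.",
        default_params("RL-GF", alpha=4.5, r=0.84),
        gaussian_kernels(sigma_w=0.025, sigma_f=0.1, sigma_r=0.15),
        unit_grid,
        extras={"seed_mode": 2},
    )
    presets["fig5-bottom"] = Preset(
        "fig5-bottom",
        "Bifurcation slice with localized resource competition "
        "(sigma_R=0.05).  The Turing band for these widths only exists for "
        "r in about (0.74, 0.80); the slice runs through its middle at "
        "r=0.77.",
        default_params("RL-GF", alpha=4.5, r=0.77),
        gaussian_kernels(sigma_w=0.025, sigma_f=0.1, sigma_r=0.05),
        unit_grid,
        extras={"seed_mode": 2},
    )

    presets["fig6"] = Preset(
        "fig6",
        "Kernel-width persistence scan: sigma_W=0.01, sigma_F=0.1 fixed, "
        "sigma_R varied over (r, alpha) space.",
        default_params("RL-GF"),
        gaussian_kernels(sigma_w=0.01, sigma_f=0.1),
        extras={"sigma_r_values": [round(0.05 - 0.0025 * i, 4) for i in range(19)],
                "r_range": (0.05, 1.0), "alpha_range": (1.0, 6.0)},
    )

    return presets


PRESETS: dict[str, Preset] = _build()


def load_preset(name: str) -> Preset:
    """Fetch a preset by name; unknown names list the alternatives."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
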