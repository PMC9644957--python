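"""Two-dimensional lever mechanics of the jaw.

Bite force at a tooth-row position is the total muscle force scaled by the
mechanical advantage at that position,

    F = F_total * A,    A = in_lever / out_lever,

where the in-lever is the jaw-joint-to-adductor-insertion distance and the
out-lever the jaw-joint-to-bite-point distance.  ``A`` is dimensionless and
lies in (0, 1) for a plausible jaw.  Specimen fixtures carry the printed
mechanical advantages directly (in-lever lengths are not printed); the
out-lever implied for the back-of-tooth-row position is derived, not asserted
as anatomy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources as _resources

import numpy as np
import pandas as pd

__all__ = [
    "LeverGeometry",
    "BiteProfile",
    "mechanical_advantage",
    "bite_force",
    "bite_profile",
    "load_lever_table",
    "lever_from_fixture",
]


def mechanical_advantage(in_lever: float, out_lever: float) -> float:
    """Ratio of in-lever to out-lever; the metric for biting ability."""
    if not in_lever > 0:
        raise ValueError(f"in_lever must be > 0, got {in_lever!r}")
    if not out_lever > 0:
        raise ValueError(f"out_lever must be > 0, got {out_lever!r}")
    return in_lever / out_lever


def bite_force(F_total: float, A: float) -> float:
    """F = F_total * A, unrounded (rounding at presentation only)."""
    if F_total < 0:
        raise ValueError(f"F_total must be >= 0, got {F_total!r}")
    if not A > 0:
        raise ValueError(f"mechanical advantage must be > 0, got {A!r}")
    if A > 1:
        warnings.warn(
            f"mechanical advantage {A:.3f} > 1: lever geometry implausible (in-lever "
            "longer than out-lever)",
            stacklevel=2,
        )
    return F_total * A


@dataclass(frozen=True)
class LeverGeometry:
    """Jaw lever arms (mm).  ``out_lever_tip`` is the total jaw length."""

    in_lever: float
    out_lever_tip: float
    out_lever_back: float

    def __post_init__(self) -> None:
        if not 0 < self.in_lever < self.out_lever_back <= self.out_lever_tip:
            raise ValueError(
                "lever geometry must satisfy 0 < in_lever < out_lever_back <= out_lever_tip, got "
                f"in={self.in_lever}, back={self.out_lever_back}, tip={self.out_lever_tip}"
            )

    @property
    def advantage_tip(self) -> float:
        return mechanical_advantage(self.in_lever, self.out_lever_tip)

    @property
    def advantage_back(self) -> float:
        return mechanical_advantage(self.in_lever, self.out_lever_back)

    def advantage_at(self, out_lever: float) -> float:
        if not 0 < out_lever <= self.out_lever_tip:
            raise ValueError(
                f"bite position {out_lever} mm lies beyond the snout tip ({self.out_lever_tip} mm)"
            )
        return mechanical_advantage(self.in_lever, out_lever)


@dataclass(frozen=True)
class BiteProfile:
    """Bite-force estimates along the tooth row for one specimen."""

    specimen: str
    F_total: float  # N
    forces: dict[str, float]  # position name -> N, unrounded

    def rounded(self) -> dict[str, int]:
        from ichthyofea.muscles import round_half_away

        return {k: int(round_half_away(v)) for k, v in self.forces.items()}


def bite_profile(
    lever: LeverGeometry,
    F_total: float,
    positions: dict[str, float] | None = None,
    specimen: str = "",
) -> BiteProfile:
    """Per-position bite forces F_total * in_lever / out_lever(position).

    ``positions`` maps names to out-lever distances (mm) from the jaw joint;
    defaults to the tip and back of the tooth row.  Force strictly increases
    from the tip toward the joint (inverse proportionality to the out-lever).
    """
    if positions is None:
        positions = {"tip_of_tooth_row": lever.out_lever_tip, "back_of_tooth_row": lever.out_lever_back}
    forces = {name: bite_force(F_total, lever.advantage_at(pos)) for name, pos in positions.items()}
    return BiteProfile(specimen=specimen, F_total=F_total, forces=forces)


def summed_bite_reaction(field, mesh, bite_set: str) -> dict:
    """Reaction-force measures at the constrained bite nodes of a solved case.

    Used for the lever/FEA consistency check: the summed vertical (dorsoventral)
    reaction at the bite constraint is the solver's analogue of the lever-model
    bite force.  Also reports the net reaction vector and the sum of nodal
    reaction magnitudes for context.
    """
    ids = np.asarray(mesh.node_sets[bite_set])
    mask = np.isin(field.reaction_nodes, ids)
    r = field.reactions[mask]
    net = r.sum(axis=0)
    return {
        "vertical_N": float(abs(net[2])),
        "net_vector_N": net,
        "net_magnitude_N": float(np.linalg.norm(net)),
        "sum_nodal_magnitudes_N": float(np.linalg.norm(r, axis=1).sum()),
        "n_nodes": int(mask.sum()),
    }


def load_lever_table(path: str | None = None) -> pd.DataFrame:
    if path is None:
        ref = _resources.files("ichthyofea").joinpath("data/levers.csv")
        with ref.open() as fh:
            return pd.read_csv(fh)
    return pd.read_csv(path)


def lever_from_fixture(specimen: str, path: str | None = None) -> LeverGeometry:
    """Lever geometry reconstructed from the fixture: the printed tip
    mechanical advantage defines the in-lever via the total jaw length."""
    df = load_lever_table(path)
    row = df[df["specimen"] == specimen]
    if row.empty:
        raise ValueError(f"no lever fixture for specimen {specimen!r}")
    row = row.iloc[0]
    in_lever = float(row.mechanical_advantage_tip) * float(row.out_lever_tip_mm)
    return LeverGeometry(
        in_lever=in_lever,
        out_lever_tip=float(row.out_lever_tip_mm),
        out_lever_back=float(row.out_lever_back_mm),
    )
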