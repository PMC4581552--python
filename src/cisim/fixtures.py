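"""Packaged synthetic fixtures: four electrode arrays and three cochleae.

The four curling profiles span the full range of curling behaviour used in
the simulation study — two units with pronounced curling (RE01, RE08,
distinguished by unit-to-unit variability), one moderate (RE06) and one with
the flattest profile and the straightest start configuration (RE07).  The
three cochleae are the small, medium and large synthetic anatomies (by
Escudé distance A).  Fixture geometry is calibrated so that for every
(array, cochlea) pair a low-overlap insertion plan exists.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

from .cochlea import SIZE_PRESETS, CochleaContour2D, synthesize_cochlea
from .electrode import CurlingProfile, synthesize_curling_profile
from . import io as cio

__all__ = ["ARRAY_LABELS", "make_profiles", "make_cochleae", "make_fixtures"]

# archetype per published-style unit label
ARRAY_LABELS = {
    "RE01": "pronounced",
    "RE06": "moderate",
    "RE07": "flat",
    "RE08": "pronounced",
}


def make_profiles(seed: int = 0) -> dict[str, CurlingProfile]:
    """The four array fixtures; deterministic per seed.  The two pronounced
    units get distinct variability sub-seeds so their start bow and
    manufactured curl differ slightly, like physically distinct implants."""
    out = {}
    for i, (label, archetype) in enumerate(sorted(ARRAY_LABELS.items())):
        sub = (seed * 101 + i) % (2**31 - 1)
        prof = synthesize_curling_profile(archetype, variability_seed=sub)
        prof.label = label
        prof.config = dataclasses.replace(prof.config, label=label)
        out[label] = prof
    return out


def make_cochleae() -> dict[str, CochleaContour2D]:
    """Small / medium / large synthetic cochleae (deterministic)."""
    return {size: synthesize_cochlea(size=size) for size in SIZE_PRESETS}


def make_fixtures(seed: int = 0, outdir: str | Path = "fixtures") -> dict:
    """Write the 4 profile files and 3 contour files; byte-identical for a
    given seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"profiles": {}, "cochleae": {}}
    for label, prof in make_profiles(seed).items():
        paths["profiles"][label] = cio.write_profile(prof, outdir / f"profile_{label}.csv")
    for size, contour in make_cochleae().items():
        paths["cochleae"][size] = cio.write_contour(contour, outdir / f"cochlea_{size}.csv")
    return paths
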