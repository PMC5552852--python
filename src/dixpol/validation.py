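"""Built-in self-validation: ground-truth recovery on synthetic crystals.

The recovery grid drives the complete pipeline -- generate, write, re-read,
expand crystal symmetry, detect head-to-tail bridges, assemble
protofilaments, classify the architecture, measure screw parameters --
over a lattice of study conditions (rise 5/11.43/20 A; twist +/-30,
+/-51.43, +/-60 deg; single and double helices; coordinate noise sigma 0
and 0.2 A) and compares every outcome against the generator's exact ground
truth.  Results come back as plain records so callers (the test suite, the
acceptance script) can apply their own assertions.

For noisy fixtures the recovered rise (A) and twist (deg) are expected
within 3*sigma/sqrt(n) of truth, n being the number of consecutive-pair
screws averaged -- the usual standard-error scaling for a mean of n noisy
rigid-body estimates.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass

import numpy as np

from .assembly import build_filaments, detect_head_to_tail, expand_neighborhood
from .geometry import helix_parameters
from .strands import DEFAULT_STRAND_DEFS
from .structure_model import read_structure
from .synthetic import FilamentSpec, generate_filament, write_fixture

__all__ = ["GRID_RISES", "GRID_TWISTS", "GRID_SIGMAS", "RecoveryRecord", "helix_recovery_grid"]

GRID_RISES = (5.0, 11.43, 20.0)
GRID_TWISTS = (-60.0, -51.43, -30.0, 30.0, 51.43, 60.0)
GRID_SIGMAS = (0.0, 0.2)
GRID_N_SUBUNITS = 5
GRID_RADIUS = 10.0


@dataclass
class RecoveryRecord:
    rise: float
    twist: float
    sigma: float
    double: bool
    seed: int
    architecture_truth: str
    architecture_found: str
    rise_error: float
    twist_error: float
    n_pairs: int

    @property
    def architecture_correct(self) -> bool:
        return self.architecture_truth == self.architecture_found

    @property
    def noise_bound(self) -> float:
        """3*sigma/sqrt(n) tolerance for noisy recovery (A or deg)."""
        return 3.0 * self.sigma / np.sqrt(max(self.n_pairs, 1))


def _run_cell(spec: FilamentSpec, workdir: str | None) -> RecoveryRecord:
    structure, truth = generate_filament(spec)
    if workdir is not None:
        # exercise the file path too; note coordinate formats carry 3
        # decimals, so exact (1e-6) recovery is only meaningful in memory
        paths = write_fixture(structure, truth, workdir, basename=f"cell_{spec.seed}")
        st = read_structure(paths["coordinates"])
    else:
        st = structure
    copies = expand_neighborhood(st, radius=GRID_RADIUS)
    edges = detect_head_to_tail(copies, DEFAULT_STRAND_DEFS["toy"])
    model = build_filaments(copies, edges)
    hp = helix_parameters(model)
    twist_err = abs(
        (hp.twist - truth.helix.twist + 180.0) % 360.0 - 180.0
    )
    return RecoveryRecord(
        rise=spec.rise,
        twist=spec.twist,
        sigma=spec.noise_sigma,
        double=spec.second_strand is not None,
        seed=spec.seed,
        architecture_truth=truth.architecture,
        architecture_found=model.architecture,
        rise_error=abs(hp.rise - truth.helix.rise),
        twist_error=twist_err,
        n_pairs=hp.n_pairs_averaged,
    )


def helix_recovery_grid(
    base_seed: int = 0,
    rises=GRID_RISES,
    twists=GRID_TWISTS,
    sigmas=GRID_SIGMAS,
    n_subunits: int = GRID_N_SUBUNITS,
    via_files: bool = False,
) -> list[RecoveryRecord]:
    """Run the full pipeline over the recovery grid; one record per cell.

    With ``via_files`` fixtures are round-tripped through PDB files first,
    which limits agreement to the format's 3-decimal coordinate precision;
    the default in-memory run supports exact (1e-6) recovery checks.  Seeds
    are derived deterministically from ``base_seed``.
    """
    records: list[RecoveryRecord] = []
    tmp = tempfile.mkdtemp(prefix="dixpol-grid-") if via_files else None
    try:
        idx = 0
        for rise in rises:
            for twist in twists:
                for double in (False, True):
                    for sigma in sigmas:
                        seed = (base_seed * 10_000 + idx) % (2**31)
                        idx += 1
                        spec = FilamentSpec(
                            rise=rise,
                            twist=twist,
                            n_subunits=n_subunits,
                            second_strand=(180.0, rise / 2.0) if double else None,
                            noise_sigma=sigma,
                            seed=seed,
                        )
                        records.append(_run_cell(spec, tmp))
    finally:
        if tmp is not None:
            import shutil

            shutil.rmtree(tmp, ignore_errors=True)
    return records
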