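import numpy as np
import pytest

from gagmap.structio import AtomRecord, Residue, ResidueKey, StructureEnsemble
from gagmap.synth import SynthSpec, gen_toy_complex_ensemble


@pytest.fixture(scope="session")
def toy_complex():
    """Default planted toy complex (100 frames, 5 planted pairs)."""
    return gen_toy_complex_ensemble(SynthSpec(seed=1))


def random_hbond_ensemble(rng: np.random.Generator, n_residues: int = 10,
                          n_frames: int = 1, box: float = 8.0) -> StructureEnsemble:
    """Random dense ensemble for H-bond detector stress tests.

    Each residue holds an N (with one H), an O and a C in a small box so
    donor-acceptor contacts at all distances/angles occur by chance; half the
    residues are protein, half glycan.
    """
    residues = []
    coords = []
    serial = 0
    for i in range(n_residues):
        role = "protein" if i < n_residues // 2 else "glycan"
        chain = "A" if role == "protein" else "B"
        key = ResidueKey(chain, i + 1, "RES", role)
        center = rng.uniform(0, box, 3)
        pos_n = center + rng.normal(0, 1.0, 3)
        pos_h = pos_n + rng.normal(0, 0.5, 3) * 0.7
        pos_o = center + rng.normal(0, 1.0, 3)
        pos_c = center + rng.normal(0, 1.0, 3)
        atoms = [
            AtomRecord(serial + 1, "N", "N", pos_n, bonded_hydrogens=[serial + 2]),
            AtomRecord(serial + 2, "H", "H", pos_h),
            AtomRecord(serial + 3, "O", "O", pos_o),
            AtomRecord(serial + 4, "C", "C", pos_c),
        ]
        serial += 4
        residues.append(Residue(key=key, atoms=atoms))
        coords.extend([pos_n, pos_h, pos_o, pos_c])
    base = np.array(coords)
    frames = base[None] + rng.normal(0, 0.8, (n_frames, len(base), 3))
    return StructureEnsemble(residues=residues, frames=frames)
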