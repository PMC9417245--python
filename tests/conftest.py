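import numpy as np
import pytest

from dimerpipe.core_io import Ensemble, StructureFrame
from dimerpipe.synthetic import build_chain_frame


@pytest.fixture
def helix_frame() -> StructureFrame:
    """Ideal 12-residue alpha helix."""
    n = 12
    return build_chain_frame(np.full(n, -57.0), np.full(n, -47.0))


@pytest.fixture
def extended_frame() -> StructureFrame:
    """Fully extended 10-residue chain."""
    n = 10
    return build_chain_frame(np.full(n, -180.0), np.full(n, 180.0))


@pytest.fixture
def hairpin_frame() -> StructureFrame:
    """Two-strand antiparallel beta hairpin at ideal strand geometry.

    Turn dihedrals chosen so the strands register and form cross-strand
    hydrogen bonds.
    """
    n = 12
    phi = np.full(n, -139.0)
    psi = np.full(n, 135.0)
    phi[5], psi[5] = 75.0, 45.0
    phi[6], psi[6] = 90.0, 0.0
    return build_chain_frame(phi, psi)


def two_bead_dimer(separation: float) -> StructureFrame:
    """Minimal two-chain system: one CA bead per chain."""
    return StructureFrame(
        coords=np.array([[0.0, 0.0, 0.0], [separation, 0.0, 0.0]]),
        atom_names=np.array(["CA", "CA"], dtype=object),
        residue_index=np.array([0, 0]),
        residue_name=np.array(["ALA", "ALA"], dtype=object),
        chain_id=np.array(["A", "B"], dtype=object),
    )


def single_frame_ensemble(frame: StructureFrame) -> Ensemble:
    return Ensemble(frames=[frame])
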