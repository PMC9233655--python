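import numpy as np
import pytest

from sterolsweep import structure_io as sio
from sterolsweep import synthetic_data as sd


def minimal_opm_atoms(dum_z=14.2, n_dum_per_layer=8, n_protein=24, jitter=None):
    """24 protein atoms on a ring plus two planar DUM layers."""
    rng = np.random.default_rng(5)
    atoms = []
    serial = 0
    for i in range(n_protein):
        serial += 1
        angle = 2 * np.pi * i / n_protein
        atoms.append(
            sio.Atom(
                serial,
                ["N", "CA", "C", "O"][i % 4],
                ["N", "C", "C", "O"][i % 4],
                "ALA",
                i // 4 + 1,
                "A",
                (5 * np.cos(angle), 5 * np.sin(angle), -12.0 + i),
                het=False,
            )
        )
    resseq = 100
    for z in (dum_z, -dum_z):
        for k in range(n_dum_per_layer):
            serial += 1
            resseq += 1
            dz = rng.normal(0.0, jitter) if jitter else 0.0
            atoms.append(
                sio.Atom(
                    serial, "DUM", "N", "DUM", resseq, "Z",
                    (4.0 * k - 14.0, 3.0, z + dz), het=True,
                )
            )
    return atoms


@pytest.fixture
def opm_text():
    return sio.write_pdb(sio.OrientedStructure(minimal_opm_atoms()))


@pytest.fixture(scope="session")
def bundle():
    return sd.make_membrane_bundle(seed=0)


@pytest.fixture(scope="session")
def prepared_bundle(bundle):
    return sio.convert_dummies_to_donor_layers(bundle)
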