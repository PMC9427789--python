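import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from epidock.alascan import Bin, FoldChangeRecord, HotspotTable
from epidock.structmodel import AtomRecord, Residue, StructureModel

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def build_residue(cid, num, name, atoms, icode="", serial_start=1):
    """Residue from a list of (atom_name, element, xyz)."""
    key = (cid, num, icode)
    return Residue(
        key=key,
        name=name,
        atoms=[
            AtomRecord(
                serial=serial_start + i,
                name=aname,
                element=el,
                residue_key=key,
                coordinates=np.asarray(xyz, dtype=float),
            )
            for i, (aname, el, xyz) in enumerate(atoms)
        ],
    )


def build_chain(cid, spec):
    """Chain from [(num, icode, resname, [(atom, element, xyz), ...]), ...]."""
    return [
        build_residue(cid, num, name, atoms, icode=icode, serial_start=10 * j)
        for j, (num, icode, name, atoms) in enumerate(spec)
    ]


@pytest.fixture(scope="session")
def fv_complex():
    """Reference mini Fv-antigen complex with known contact truth."""
    from epidock.synthetic import make_fv_complex

    return make_fv_complex()


def truth_hotspot_table(annotation, true_antibody_contacts):
    """Scanning table over all annotated Fv residues: contacts are knockouts."""
    records = {}
    for key in annotation.numbering:
        positive = key in true_antibody_contacts
        mid = f"{key[0]}{key[1]}{key[2]}A"
        records[mid] = FoldChangeRecord(
            mutant_id=mid,
            mode="kd_ratio",
            fold=None if positive else 1.2,
            censored=positive,
            censor_bound=100.0,
            bin=Bin.STAR3 if positive else Bin.NONE,
            residue_key=key,
        )
    return HotspotTable(records)
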