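import textwrap

import numpy as np
import pytest

import hrpf


def _atom_line(serial, name, resname, chain, resnum, x, y, z, occ=1.0, altloc=" ",
               element=None):
    element = element or name[0]
    return (f"ATOM  {serial:5d} {name:<4s}{altloc}{resname:<3s} {chain}{resnum:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00          {element:>2s}")


@pytest.fixture
def two_model_pdb(tmp_path):
    """Two-MODEL PDB: 3 residues (ALA, GLY, TRP); GLY has backbone only."""
    lines = ["HELIX    1   1 ALA A    1  GLY A    2  1                                   2"]
    for imodel, dz in ((1, 0.0), (2, 0.7)):
        lines.append(f"MODEL     {imodel:4d}")
        s = 1
        for resnum, resname, has_cb in ((1, "ALA", True), (2, "GLY", False), (3, "TRP", True)):
            x0 = 3.8 * (resnum - 1)
            lines.append(_atom_line(s, "N", resname, "A", resnum, x0 - 0.5, 1.2, dz)); s += 1
            lines.append(_atom_line(s, "CA", resname, "A", resnum, x0, 0.0, dz, element="C")); s += 1
            lines.append(_atom_line(s, "C", resname, "A", resnum, x0 + 1.2, 0.8, dz, element="C"))
            s += 1
            if has_cb:
                lines.append(_atom_line(s, "CB", resname, "A", resnum, x0, -1.0, dz + 1.1,
                                        element="C"))
                s += 1
        lines.append("ENDMDL")
    lines.append("END")
    p = tmp_path / "two_model.pdb"
    p.write_text("\n".join(lines) + "\n")
    return p


@pytest.fixture
def altloc_hetatm_pdb(tmp_path):
    """Single model with an altLoc'd CB (B has higher occupancy) and a HETATM."""
    lines = [
        _atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, element="C"),
        _atom_line(2, "CB", "ALA", "A", 1, 1.0, 0.0, 0.0, occ=0.4, altloc="A", element="C"),
        _atom_line(3, "CB", "ALA", "A", 1, 2.0, 0.0, 0.0, occ=0.6, altloc="B", element="C"),
        _atom_line(4, "CA", "LEU", "A", 2, 3.8, 0.0, 0.0, element="C"),
        _atom_line(5, "CB", "LEU", "A", 2, 3.8, 1.5, 0.0, element="C"),
        "HETATM    6  O   HOH A 100       9.000   9.000   9.000  1.00  0.00           O",
        "END",
    ]
    p = tmp_path / "altloc.pdb"
    p.write_text("\n".join(lines) + "\n")
    return p


@pytest.fixture
def native60():
    return hrpf.make_ideal_native(60, fold="helix-bundle", seed=11)


@pytest.fixture
def pf_noise_free(native60):
    return hrpf.make_synthetic_pf(native60, hrpf.SyntheticPFConfig(seed=11))


def random_model(rng, n_residues=20, spread=12.0):
    """A random CA/CB cloud: geometrically unstructured but valid."""
    types = list("ACDEFGHIKLMNPQRSTVWY")
    residues = []
    for i in range(n_residues):
        ca = rng.uniform(-spread, spread, 3)
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        res_type = types[rng.integers(len(types))]
        cb = None if res_type == "G" else ca + 1.53 * direction
        n_at = ca + np.array([-1.0, 0.9, 0.2])
        c_at = ca + np.array([1.1, 0.8, -0.3])
        residues.append(hrpf.Residue(chain_id="A", seq_num=i + 1, res_type=res_type,
                                     ca=ca, cb=cb, n=n_at, c=c_at))
    return hrpf.ProteinModel(model_id=f"rand_{rng.integers(1 << 30)}", residues=residues)
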