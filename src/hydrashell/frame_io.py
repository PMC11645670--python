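"""Frame input/output: multi-model PDB and extended XYZ with a role column.

PDB is written through biotite.  Water molecules are HOH residues (O, H1,
H2); carboxylate oxygens are written as ASP OD1 atoms so that standard
tooling identifies them; remaining protein atoms are single-atom GLY
residues named after their element.  Readers accept the usual water residue
names (HOH/WAT/TIP/TIP3/SOL) and flag carboxylate oxygens on ASP/GLU
residues with atom names OD1/OD2/OE1/OE2.

The extended-XYZ dialect is self-describing: per-atom columns are
``species x y z role carbox mol``, where ``mol`` groups each water's three
atoms (-1 for non-water atoms), and the comment line carries an optional
orthorhombic ``Lattice``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .frame import Frame, Roles

WATER_RES = {"HOH", "WAT", "TIP", "TIP3", "SOL"}
CARBOX_RES = {"ASP", "GLU"}
CARBOX_ATOMS = {"OD1", "OD2", "OE1", "OE2"}
ION_RES = {"K", "CL", "NA", "POT", "CLA", "SOD"}

_ROLE_TO_PDB = {
    Roles.PROTEIN_C: ("GLY", "C", "C"),
    Roles.PROTEIN_O: ("GLY", "O", "O"),
    Roles.PROTEIN_N: ("GLY", "N", "N"),
    Roles.PROTEIN_OTHER: ("GLY", "CB", "C"),
}


def _frame_to_atom_array(frame: Frame) -> struc.AtomArray:
    n = frame.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = frame.positions.astype(np.float32)
    h_to_water = {int(h): w for w, pair in enumerate(frame.water_h) for h in pair}
    o_to_water = {int(o): w for w, o in enumerate(frame.water_o)}
    res_id = 0
    prev_water = -1
    for i in range(n):
        role = str(frame.roles[i])
        if role == Roles.WATER_O or role == Roles.WATER_H:
            w = o_to_water.get(i, h_to_water.get(i))
            if w != prev_water:
                res_id += 1
                prev_water = w
            arr.chain_id[i] = "W"
            arr.res_id[i] = res_id
            arr.res_name[i] = "HOH"
            if role == Roles.WATER_O:
                arr.atom_name[i] = "O"
                arr.element[i] = "O"
            else:
                k = 1 + list(frame.water_h[w]).index(i)
                arr.atom_name[i] = f"H{k}"
                arr.element[i] = "H"
        elif role == Roles.ION:
            res_id += 1
            prev_water = -1
            arr.chain_id[i] = "I"
            arr.res_id[i] = res_id
            arr.res_name[i] = "K"
            arr.atom_name[i] = "K"
            arr.element[i] = "K"
        else:
            res_id += 1
            prev_water = -1
            arr.chain_id[i] = "A"
            arr.res_id[i] = res_id
            if frame.carboxylate[i]:
                arr.res_name[i] = "ASP"
                arr.atom_name[i] = "OD1"
                arr.element[i] = "O"
            else:
                res_name, atom_name, element = _ROLE_TO_PDB[role]
                arr.res_name[i] = res_name
                arr.atom_name[i] = atom_name
                arr.element[i] = element
    arr.hetero[:] = False
    if frame.box is not None:
        arr.box = np.diag(frame.box).astype(np.float32)
    return arr


def write_pdb(frames: list[Frame], path) -> None:
    """Write frames as a multi-model PDB file."""
    if not frames:
        raise ValueError("no frames to write")
    stack = struc.stack([_frame_to_atom_array(f) for f in frames])
    f = pdb.PDBFile()
    f.set_structure(stack)
    f.write(str(path))


def _atom_array_to_frame(arr: struc.AtomArray, box: np.ndarray | None) -> Frame:
    n = arr.array_length()
    roles = np.empty(n, dtype="<U16")
    carbox = np.zeros(n, dtype=bool)
    water_key: dict[tuple, list] = {}
    for i in range(n):
        res = str(arr.res_name[i]).strip().upper()
        atom = str(arr.atom_name[i]).strip().upper()
        elem = str(arr.element[i]).strip().upper()
        if res in WATER_RES:
            if elem == "O" or atom.startswith("O"):
                roles[i] = Roles.WATER_O
            else:
                roles[i] = Roles.WATER_H
            key = (str(arr.chain_id[i]), int(arr.res_id[i]))
            water_key.setdefault(key, []).append(i)
        elif res in ION_RES and atom == res:
            roles[i] = Roles.ION
        elif elem == "C":
            roles[i] = Roles.PROTEIN_C
        elif elem == "O":
            roles[i] = Roles.PROTEIN_O
            carbox[i] = res in CARBOX_RES and atom in CARBOX_ATOMS
        elif elem == "N":
            roles[i] = Roles.PROTEIN_N
        else:
            roles[i] = Roles.PROTEIN_OTHER
    water_o = np.flatnonzero(roles == Roles.WATER_O)
    water_h = np.empty((len(water_o), 2), dtype=int)
    o_row = {int(o): r for r, o in enumerate(water_o)}
    for key, members in water_key.items():
        o = [i for i in members if roles[i] == Roles.WATER_O]
        h = [i for i in members if roles[i] == Roles.WATER_H]
        if len(o) != 1 or len(h) != 2:
            raise ValueError(f"water residue {key} does not have exactly O + 2H")
        water_h[o_row[o[0]]] = h
    return Frame(
        positions=arr.coord.astype(float),
        roles=roles,
        carboxylate=carbox,
        water_h=water_h,
        box=box,
        water_o=water_o,
    )


def read_pdb(path) -> list[Frame]:
    """Read a multi-model PDB file into frames."""
    f = pdb.PDBFile.read(str(path))
    stack = f.get_structure(model=None)
    box = None
    if stack.box is not None:
        b = np.asarray(stack.box)[0] if np.asarray(stack.box).ndim == 3 else np.asarray(stack.box)
        if not np.allclose(b, np.diag(np.diag(b))):
            raise ValueError("only orthorhombic boxes are supported")
        diag = np.diag(b)
        if np.any(diag > 0):
            box = diag.astype(float)
    frames = []
    for m in range(stack.stack_depth()):
        frames.append(_atom_array_to_frame(stack[m], box))
    return frames


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------

_ROLE_TO_SPECIES = {
    Roles.PROTEIN_C: "C",
    Roles.PROTEIN_O: "O",
    Roles.PROTEIN_N: "N",
    Roles.PROTEIN_OTHER: "X",
    Roles.WATER_O: "O",
    Roles.WATER_H: "H",
    Roles.ION: "K",
}


def write_xyz(frames: list[Frame], path) -> None:
    """Write frames as concatenated extended-XYZ blocks with a role column."""
    if not frames:
        raise ValueError("no frames to write")
    with Path(path).open("w") as fh:
        for frame in frames:
            mol = np.full(frame.n_atoms, -1, dtype=int)
            for w, o in enumerate(frame.water_o):
                mol[o] = w
                mol[frame.water_h[w]] = w
            props = "Properties=species:S:1:pos:R:3:role:S:1:carbox:I:1:mol:I:1"
            comment = props
            if frame.box is not None:
                a, b, c = frame.box
                comment = f'Lattice="{a} 0 0 0 {b} 0 0 0 {c}" ' + props
            fh.write(f"{frame.n_atoms}\n{comment}\n")
            for i in range(frame.n_atoms):
                x, y, z = frame.positions[i]
                fh.write(
                    f"{_ROLE_TO_SPECIES[str(frame.roles[i])]} "
                    f"{x:.8f} {y:.8f} {z:.8f} "
                    f"{frame.roles[i]} {int(frame.carboxylate[i])} {mol[i]}\n"
                )


def read_xyz(path) -> list[Frame]:
    """Read concatenated extended-XYZ blocks written by :func:`write_xyz`."""
    frames: list[Frame] = []
    lines = Path(path).read_text().splitlines()
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        n = int(lines[pos].strip())
        comment = lines[pos + 1]
        box = None
        if 'Lattice="' in comment:
            cell = [float(v) for v in comment.split('Lattice="')[1].split('"')[0].split()]
            mat = np.array(cell).reshape(3, 3)
            if not np.allclose(mat, np.diag(np.diag(mat))):
                raise ValueError("only orthorhombic lattices are supported")
            box = np.diag(mat)
        coords = np.empty((n, 3))
        roles = np.empty(n, dtype="<U16")
        carbox = np.zeros(n, dtype=bool)
        mol = np.empty(n, dtype=int)
        for i in range(n):
            parts = lines[pos + 2 + i].split()
            coords[i] = [float(v) for v in parts[1:4]]
            roles[i] = parts[4]
            carbox[i] = bool(int(parts[5]))
            mol[i] = int(parts[6])
        water_o = np.flatnonzero(roles == Roles.WATER_O)
        water_h = np.empty((len(water_o), 2), dtype=int)
        for r, o in enumerate(water_o):
            hs = np.flatnonzero((mol == mol[o]) & (roles == Roles.WATER_H))
            if len(hs) != 2:
                raise ValueError(f"water molecule {mol[o]} does not have exactly 2 H")
            water_h[r] = hs
        frames.append(
            Frame(
                positions=coords,
                roles=roles,
                carboxylate=carbox,
                water_h=water_h,
                box=box,
                water_o=water_o,
            )
        )
        pos += 2 + n
    return frames
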