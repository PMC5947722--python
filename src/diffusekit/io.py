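"""Exchange formats: PDB, hkl-I text, grid container, configs, TIFF, CCP4.

Half-integer Miller indices are stored internally as integer supercell
indices plus a per-axis sampling factor and are materialized as decimals
only in text output (``0.5 1 -1.5 <I>``).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import gemmi
import numpy as np

from .diffuse import DiffuseMap
from .lattice import Lattice, ReciprocalGrid
from .model import AtomicModel, Ensemble

__all__ = [
    "read_pdb",
    "write_pdb",
    "write_hkl",
    "read_hkl",
    "write_grid",
    "read_grid",
    "write_ccp4",
    "read_config",
    "write_config",
    "write_tiff",
    "read_tiff",
    "config_hash",
]


# -- PDB -------------------------------------------------------------------


def _lattice_from_cell(cell: gemmi.UnitCell, laue: str = "P1") -> Lattice:
    return Lattice(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma, laue_group=laue)


def read_pdb(path: str | Path) -> AtomicModel | Ensemble:
    """Read a (multi-)model PDB; the CRYST1 cell drives all geometry.

    Single-model files return an AtomicModel; multi-model files return an
    Ensemble whose reference is the first model.  Coordinates are converted
    orthogonal -> fractional via the standard orthogonalization.
    """
    st = gemmi.read_structure(str(path))
    if st.cell.a == 1.0 and st.cell.b == 1.0 and st.cell.c == 1.0 or st.cell.volume < 2.0:
        raise ValueError(
            f"{path}: missing or placeholder CRYST1 record; the unit cell is "
            "required because it drives all reciprocal-space geometry"
        )
    laue = "P4/m" if "4" in (st.spacegroup_hm or "") else "P1"
    lattice = _lattice_from_cell(st.cell, laue)
    if len(st) == 0:
        raise ValueError(f"{path}: no ATOM/HETATM records")

    def model_coords(md: gemmi.Model):
        els, frac, occ, copies, names = [], [], [], [], []
        for ci, chain in enumerate(md):
            for res in chain:
                for atom in res:
                    els.append(atom.element.name)
                    f = st.cell.fractionalize(atom.pos)
                    frac.append([f.x, f.y, f.z])
                    occ.append(atom.occ)
                    copies.append(ci)
                    names.append(atom.name)
        return els, np.array(frac), occ, copies, names

    els, frac, occ, copies, names = model_coords(st[0])
    ref = AtomicModel(
        lattice=lattice,
        elements=np.array(els, dtype=object),
        frac=frac,
        occupancy=np.array(occ),
        copy_id=np.array(copies),
        atom_names=np.array(names, dtype=object),
    )
    if len(st) == 1:
        return ref
    snaps = np.stack([model_coords(md)[1] for md in st])
    return Ensemble(model=ref, frac=snaps, meta={"source": str(path)})


def write_pdb(path: str | Path, obj: AtomicModel | Ensemble, spacegroup: str | None = None) -> None:
    """Write a model or ensemble as PDB with CRYST1 (MODEL/ENDMDL for ensembles)."""
    model = obj.model if isinstance(obj, Ensemble) else obj
    lat = model.lattice
    st = gemmi.Structure()
    st.cell = lat.gemmi_cell
    st.spacegroup_hm = spacegroup or ("P 41" if lat.laue_group == "P4/m" else "P 1")
    snapshots = obj.frac if isinstance(obj, Ensemble) else model.frac[None]
    for n, frac in enumerate(snapshots):
        md = gemmi.Model(n + 1)
        for cp in np.unique(model.copy_id):
            chain = gemmi.Chain(_chain_name(int(cp)))
            sel = np.flatnonzero(model.copy_id == cp)
            res = gemmi.Residue()
            res.name = "UNK"
            res.seqid = gemmi.SeqId(1, " ")
            for a in sel:
                atom = gemmi.Atom()
                atom.name = str(model.atom_names[a])
                atom.element = gemmi.Element(str(model.elements[a]))
                atom.occ = float(model.occupancy[a])
                cart = lat.frac_to_cart(frac[a])
                atom.pos = gemmi.Position(*cart)
                res.add_atom(atom)
            chain.add_residue(res)
            md.add_chain(chain)
        st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))


def _chain_name(i: int) -> str:
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789abcdefghijklmnopqrstuvwxyz"
    if i < len(alphabet):
        return alphabet[i]
    return alphabet[i % len(alphabet)] + str(i // len(alphabet))


# -- hkl-I text ------------------------------------------------------------


def _format_index(x: float) -> str:
    return f"{int(round(x))}" if abs(x - round(x)) < 1e-9 else f"{x:g}"


def write_hkl(path: str | Path, dmap: DiffuseMap) -> None:
    """One measured point per line: ``h k l I`` with half-integers as decimals."""
    grid = dmap.grid
    idx = grid.index_points()
    meas = dmap.measured.ravel()
    hkl = grid.physical_hkl(idx[meas])
    vals = dmap.values.ravel()[meas]
    with open(path, "w") as fh:
        for (h, k, l), v in zip(hkl, vals):
            fh.write(f"{_format_index(h)} {_format_index(k)} {_format_index(l)} {float(v)!r}\n")


def read_hkl(path: str | Path, grid: ReciprocalGrid, provenance: str = "observed") -> DiffuseMap:
    """Read h k l I text onto an existing grid (inverts write_hkl bit-exactly)."""
    values = np.zeros(grid.shape)
    measured = np.zeros(grid.shape, dtype=bool)
    sampling = np.asarray(grid.sampling, dtype=float)
    bounds = np.asarray(grid.bounds)
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{ln}: expected 'h k l I', got {line!r}")
            try:
                h, k, l, v = (float(p) for p in parts)
            except ValueError as err:
                raise ValueError(f"{path}:{ln}: malformed number in {line!r}") from err
            idx = np.array([h, k, l]) * sampling
            iidx = np.rint(idx).astype(int)
            if np.max(np.abs(idx - iidx)) > 1e-6:
                raise ValueError(
                    f"{path}:{ln}: index ({h} {k} {l}) incompatible with sampling {grid.sampling}"
                )
            if np.any(np.abs(iidx) > bounds):
                raise ValueError(f"{path}:{ln}: index outside the grid bounds {tuple(bounds)}")
            off = grid.to_dense_offset(iidx)
            values[off] = v
            measured[off] = True
    return DiffuseMap(grid=grid, values=values, measured=measured, provenance=provenance)


# -- grid container --------------------------------------------------------

GRID_FORMAT_VERSION = 1


def write_grid(path: str | Path, dmap: DiffuseMap, provenance_extra: dict | None = None) -> None:
    """Self-describing voxel-grid container (numpy .npz).

    The header fully determines the geometry: cell, Laue group,
    multiplicity, sampling factors, d_min, provenance and mask convention
    (True = measured).  Round-trips bit-exactly.
    """
    lat = dmap.grid.lattice
    header = {
        "format_version": GRID_FORMAT_VERSION,
        "cell": [lat.a, lat.b, lat.c, lat.alpha, lat.beta, lat.gamma],
        "laue_group": lat.laue_group,
        "multiplicity": list(lat.multiplicity),
        "sampling": list(dmap.grid.sampling),
        "d_min": dmap.grid.d_min,
        "provenance": dmap.provenance,
        "mask_convention": "true=measured",
        "meta": {**{k: v for k, v in dmap.meta.items() if _jsonable(v)}, **(provenance_extra or {})},
    }
    np.savez_compressed(
        path,
        header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
        values=dmap.values,
        measured=dmap.measured,
    )


def read_grid(path: str | Path) -> DiffuseMap:
    with np.load(path) as npz:
        header = json.loads(bytes(npz["header"]).decode())
        values = npz["values"]
        measured = npz["measured"]
    if header.get("format_version") != GRID_FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported grid format version")
    a, b, c, al, be, ga = header["cell"]
    lat = Lattice(
        a, b, c, al, be, ga,
        laue_group=header["laue_group"],
        multiplicity=tuple(header["multiplicity"]),
    )
    grid = ReciprocalGrid(lat, d_min=header["d_min"], sampling=tuple(header["sampling"]))
    if grid.shape != values.shape:
        raise ValueError(f"{path}: header geometry inconsistent with stored arrays")
    return DiffuseMap(
        grid=grid,
        values=values,
        measured=measured,
        provenance=header["provenance"],
        meta=header.get("meta", {}),
    )


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


# -- CCP4 maps -------------------------------------------------------------


def write_ccp4(path: str | Path, values: np.ndarray, cell: Lattice) -> None:
    """Write a real-space map (e.g. a Patterson) in CCP4/MRC format."""
    grid = gemmi.FloatGrid(np.ascontiguousarray(values, dtype=np.float32))
    grid.set_unit_cell(cell.gemmi_cell)
    grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))


# -- plain-text key=value configs ------------------------------------------


def read_config(path: str | Path) -> dict:
    """Parse a plain-text ``key = value`` config (JSON-typed values).

    Values are parsed as JSON when possible (numbers, lists, booleans) and
    kept as strings otherwise.  Lines starting with '#' are comments.
    """
    cfg: dict = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected 'key = value', got {line!r}")
            key, _, val = line.partition("=")
            val = val.strip()
            try:
                cfg[key.strip()] = json.loads(val)
            except json.JSONDecodeError:
                cfg[key.strip()] = val
    return cfg


def write_config(path: str | Path, cfg: dict) -> None:
    with open(path, "w") as fh:
        for key, val in cfg.items():
            fh.write(f"{key} = {json.dumps(val)}\n")


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


# -- detector images -------------------------------------------------------


def write_tiff(path: str | Path, img) -> None:
    """16-bit grayscale TIFF; a companion ``<path>.mask.tif`` holds the mask."""
    import tifffile

    tifffile.imwrite(str(path), img.as_uint16())
    if img.mask.any():
        tifffile.imwrite(str(path) + ".mask.tif", img.mask.astype(np.uint8))


def read_tiff(path: str | Path, geometry=None, orientation=None):
    import tifffile

    from .images import DetectorImage

    pixels = tifffile.imread(str(path)).astype(float)
    mask_path = Path(str(path) + ".mask.tif")
    mask = tifffile.imread(str(mask_path)).astype(bool) if mask_path.exists() else None
    return DetectorImage(pixels=pixels, mask=mask, geometry=geometry, orientation=orientation)
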