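"""End-to-end pipeline: crystal -> ensemble -> diffuse maps -> analyses.

Runs the stages in their natural order (synthesis, structure factors,
chunked Guinier accumulation, isotropic/anisotropic decomposition, Laue
symmetrization, comparison statistics, Patterson transforms, rigid-body
fits) with one seed, logging each stage and embedding the config hash and
seed in every artifact.  Chunked accumulation pools exact moments, so the
merged diffuse map is invariant to the chunk count.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import io as dio
from .diffuse import (
    GuinierAccumulator,
    anisotropic_map,
    cc_sym,
    merge_partial,
    radial_profile,
    symmetrize,
)
from .lattice import Lattice, ReciprocalGrid
from .patterson import anisotropic_bragg, patterson_fft, section
from .rigid import per_copy_fits, rotation_statistics
from .structure_factors import ensemble_structure_factors, mean_intensities
from .synthetic import (
    MotionModel,
    build_supercell,
    expand_p41,
    make_toy_asymmetric_unit,
    sample_ensemble,
)

logger = logging.getLogger("diffusekit.pipeline")

DEFAULT_CONFIG = {
    "seed": 0,
    "cell": [18.0, 18.0, 24.0, 90.0, 90.0, 90.0],
    "n_atoms": 20,
    "extent": 8.0,
    "supercell": [2, 2, 2],
    "motion": "liquid_like",
    "sigma": 0.3,
    "gamma": 5.0,
    "rot_sd": 2.0,
    "trans_sd": 0.1,
    "n_snapshots": 500,
    "chunks": 10,
    "d_min": 2.0,
    "patterson": True,
    "rigid": True,
}


def _motion_from_config(cfg: dict) -> MotionModel:
    kind = cfg["motion"]
    return MotionModel(
        kind=kind,
        sigma=cfg.get("sigma", 0.3),
        gamma=cfg.get("gamma", 5.0),
        rot_sd=cfg.get("rot_sd", 2.0),
        trans_sd=cfg.get("trans_sd", 0.1),
    )


def pipeline_run(config: dict | str | Path, outdir: str | Path) -> dict:
    """Execute the pipeline; returns a dict of in-memory results.

    ``config`` is a dict or a path to a key=value text file; unset keys take
    the defaults above.  Artifacts (PDB, grid files, CSV tables, CCP4 maps,
    a JSON manifest) are written under ``outdir``.
    """
    if not isinstance(config, dict):
        config = dio.read_config(config)
    cfg = {**DEFAULT_CONFIG, **config}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = dio.config_hash(cfg)
    seed = int(cfg["seed"])
    stamp = {"config_hash": chash, "seed": seed}
    results: dict = {"config": cfg}

    def stage(name):
        logger.info("stage %-14s config=%s seed=%d", name, chash, seed)

    try:
        stage("synthesize")
        a, b, c, al, be, ga = cfg["cell"]
        cell = Lattice(a, b, c, al, be, ga, laue_group="P4/m")
        au = make_toy_asymmetric_unit(int(cfg["n_atoms"]), float(cfg["extent"]), seed, cell=cell)
        unit = expand_p41(au)
        supercell = build_supercell(unit, tuple(cfg["supercell"]))
        dio.write_pdb(outdir / "unit_cell.pdb", unit)
        dio.write_pdb(outdir / "supercell.pdb", supercell)
        results["supercell"] = supercell

        stage("ensemble")
        motion = _motion_from_config(cfg)
        ensemble = sample_ensemble(supercell, motion, int(cfg["n_snapshots"]), seed + 1)
        results["ensemble"] = ensemble

        stage("guinier")
        grid = ReciprocalGrid.for_model(supercell, d_min=float(cfg["d_min"]))
        n_chunks = max(1, int(cfg["chunks"]))
        bounds = np.linspace(0, ensemble.n_snapshots, n_chunks + 1).astype(int)
        partials = []
        sf_iter = ensemble_structure_factors(ensemble, grid)
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            acc = GuinierAccumulator(grid)
            for _ in range(hi - lo):
                acc.add(next(sf_iter))
            if acc.n:
                partials.append(acc)
        diffuse = merge_partial(partials)
        dio.write_grid(outdir / "diffuse.grid.npz", diffuse, provenance_extra=stamp)
        results["diffuse"] = diffuse

        stage("decompose")
        profile = radial_profile(diffuse)
        aniso = anisotropic_map(diffuse, profile)
        dio.write_grid(outdir / "diffuse_anisotropic.grid.npz", aniso, provenance_extra=stamp)
        results["profile"] = profile
        results["anisotropic"] = aniso

        stage("symmetrize")
        sym = symmetrize(aniso, "P4/m")
        dio.write_grid(outdir / "diffuse_anisotropic_sym.grid.npz", sym, provenance_extra=stamp)
        dio.write_hkl(outdir / "diffuse_anisotropic_sym.hkl", sym)
        results["symmetrized"] = sym

        stage("statistics")
        stats = {
            "cc_sym": float(cc_sym(diffuse, "P4/m")),
            "n_snapshots": ensemble.n_snapshots,
            "n_measured": int(diffuse.measured.sum()),
            **stamp,
        }
        results["stats"] = stats

        if cfg.get("patterson"):
            stage("patterson")
            pat = patterson_fft(sym)
            dio.write_ccp4(outdir / "patterson_diffuse.ccp4", pat.values, pat.cell)
            np.savetxt(outdir / "patterson_x0_section.txt", section(pat, "x", 0))
            # Bragg route on the unit-cell integer lattice
            unit_grid = ReciprocalGrid(cell, d_min=float(cfg["d_min"]))
            bragg = mean_intensities(
                ensemble_structure_factors(
                    _unit_view(ensemble, unit), unit_grid
                )
            )
            bragg_aniso = anisotropic_bragg(bragg)
            pat_bragg = patterson_fft(symmetrize(bragg_aniso.map, "P4/m"))
            dio.write_ccp4(outdir / "patterson_bragg.ccp4", pat_bragg.values, pat_bragg.cell)
            results["patterson_diffuse"] = pat
            results["patterson_bragg"] = pat_bragg

        if cfg.get("rigid"):
            stage("rigid")
            fits = per_copy_fits(ensemble, stride=max(1, ensemble.n_snapshots // 250))
            table = rotation_statistics(fits)
            table.to_csv(outdir / "rigid_body.csv")
            results["rigid"] = table

        stats_path = outdir / "stats.json"
        stats_path.write_text(json.dumps(stats, indent=2))
        (outdir / "manifest.json").write_text(
            json.dumps({"artifacts": sorted(p.name for p in outdir.iterdir()), **stamp}, indent=2)
        )
    except Exception as err:
        raise RuntimeError(f"pipeline stage failed: {err}") from err
    return results


def _unit_view(ensemble, unit_model):
    """Project supercell snapshots onto the first unit-cell copy set.

    Used for the Bragg (mean-structure) route, which lives on the unit-cell
    integer lattice: the supercell fractional coordinates of the first tile
    are rescaled to unit-cell fractions.
    """
    from .model import Ensemble

    n_unit = unit_model.n_atoms
    mult = np.asarray(ensemble.model.lattice.multiplicity, dtype=float)
    frac_unit = ensemble.frac[:, :n_unit, :] * mult
    return Ensemble(model=unit_model, frac=frac_unit, seed=ensemble.seed)
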