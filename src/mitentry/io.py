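"""File contracts: parameter sets, tables, phosphosite TSVs and movies.

Everything is plain text except movies (multi-page TIFF via tifffile).
Phosphosite tables use a documented TSV schema; MaxQuant-style column
names are accepted through an alias map so exported "Phospho (STY)"-like
tables can be ingested directly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from mitentry.imaging import LabeledMovie
from mitentry.model import CellTrajectory, KineticParameters
from mitentry.phospho import PhosphositeTable

__all__ = [
    "read_parameters",
    "write_parameters",
    "write_trajectory",
    "read_trajectory_frame",
    "write_phospho_tables",
    "read_phospho_tables",
    "write_movie",
    "read_movie",
    "write_manifest",
]

#: MaxQuant-style aliases for the site-table columns
SITE_COLUMN_ALIASES = {
    "Leading proteins": "protein",
    "Protein": "protein",
    "Gene names": "gene",
    "Amino acid": "residue",
    "Position": "position",
    "Localization prob": "localization_prob",
    "Potential contaminant": "contaminant",
    "Reverse": "reverse",
    "Multiplicity": "multiplicity",
}


def write_parameters(params: KineticParameters | dict, path) -> None:
    """One named block per scenario: {"name": {param: value, ...}}."""
    if isinstance(params, KineticParameters):
        params = {"default": params.to_dict()}
    blocks = {
        name: (p.to_dict() if isinstance(p, KineticParameters) else dict(p))
        for name, p in params.items()
    }
    Path(path).write_text(json.dumps(blocks, indent=2) + "\n")


def read_parameters(path, name: str = "default") -> KineticParameters:
    blocks = json.loads(Path(path).read_text())
    if name not in blocks:
        raise KeyError(f"no parameter block {name!r} in {path}; has {sorted(blocks)}")
    return KineticParameters.from_dict(blocks[name])


def write_trajectory(trajectory: CellTrajectory, path) -> None:
    df = trajectory.to_dataframe()
    df.to_csv(path, index=False)


def read_trajectory_frame(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_phospho_tables(table: PhosphositeTable, out_dir, prefix: str = "phospho") -> dict:
    """Write sites+intensities and the sample annotation as TSV; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sites_path = out / f"{prefix}_sites.tsv"
    design_path = out / f"{prefix}_design.tsv"
    merged = table.sites.join(table.intensities)
    merged.to_csv(sites_path, sep="\t", index=True)
    table.samples.to_csv(design_path, sep="\t", index=True)
    return {"sites": sites_path, "design": design_path}


def read_phospho_tables(sites_path, design_path) -> PhosphositeTable:
    """Read a site TSV (metadata + intensity columns) and a design TSV.

    The design's index names the intensity columns; any metadata column
    matching a MaxQuant alias is renamed to the internal schema.
    """
    samples = pd.read_csv(design_path, sep="\t", index_col=0)
    merged = pd.read_csv(sites_path, sep="\t", index_col=0)
    merged = merged.rename(columns=SITE_COLUMN_ALIASES)
    sample_cols = [c for c in merged.columns if c in set(samples.index)]
    meta_cols = [c for c in merged.columns if c not in set(samples.index)]
    sites = merged[meta_cols].copy()
    for flag in ("contaminant", "reverse"):
        if flag in sites:
            col = sites[flag]
            if col.dtype == object:  # MaxQuant uses "+" markers
                sites[flag] = col.fillna("").astype(str).str.strip().isin(("+", "True", "true", "1"))
            else:
                sites[flag] = col.notna() & col.astype(bool)
    intensities = merged[sample_cols].astype(float)
    return PhosphositeTable(sites=sites, intensities=intensities, samples=samples)


def write_movie(movie: LabeledMovie, out_dir, prefix: str = "movie") -> dict:
    """Intensity channels and labels as multi-page TIFFs + a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, arr in movie.frames.items():
        p = out / f"{prefix}_{name}.tif"
        tifffile.imwrite(p, np.asarray(arr, dtype=np.float32),
                         photometric="minisblack")
        paths[f"channel:{name}"] = p
    lab_path = out / f"{prefix}_labels.tif"
    tifffile.imwrite(lab_path, np.asarray(movie.labels, dtype=np.int32),
                     photometric="minisblack")
    paths["labels"] = lab_path
    meta = {
        "channels": sorted(movie.frames),
        "background": movie.background,
        "frame_interval_min": movie.frame_interval_min,
    }
    meta_path = out / f"{prefix}_meta.json"
    meta_path.write_text(json.dumps(meta, indent=2) + "\n")
    paths["meta"] = meta_path
    return paths


def read_movie(out_dir, prefix: str = "movie") -> LabeledMovie:
    out = Path(out_dir)
    meta = json.loads((out / f"{prefix}_meta.json").read_text())
    frames = {
        name: tifffile.imread(out / f"{prefix}_{name}.tif").astype(float)
        for name in meta["channels"]
    }
    labels = tifffile.imread(out / f"{prefix}_labels.tif").astype(np.int32)
    return LabeledMovie(
        frames=frames,
        labels=labels,
        background={k: float(v) for k, v in meta["background"].items()},
        frame_interval_min=float(meta["frame_interval_min"]),
    )


def write_manifest(out_dir, command: str, config: dict) -> Path:
    """Provenance record written alongside every CLI run's outputs."""
    from mitentry import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "manifest.json"
    path.write_text(json.dumps({
        "command": command,
        "package_version": __version__,
        "config": config,
    }, indent=2, default=str) + "\n")
    return path
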