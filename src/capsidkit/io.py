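"""File I/O: MRC2014 volumes, TIFF/PNG sections, CSV tables, run manifests.

Volumes are written as MRC/CCP4 mode-2 float maps with the voxel size in the
header (via gemmi).  Section images go to 32-bit TIFF (quantitative) or 8-bit
PNG (preview).  Particle records and radial profiles round-trip through CSV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .phantoms import DensityVolume, SectionImage

__all__ = [
    "read_volume",
    "write_volume",
    "write_section_tiff",
    "write_section_png",
    "read_records_csv",
    "write_records_csv",
    "write_profile_csv",
    "read_profile_csv",
    "write_manifest",
]


def write_volume(volume: DensityVolume, path) -> None:
    """Write an MRC2014 (mode 2, float32) map; voxel size in the header."""
    import gemmi

    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(volume.data, dtype=np.float32))
    n = volume.data.shape[0]
    a = n * volume.voxel_size
    m.grid.unit_cell = gemmi.UnitCell(a, a, a, 90.0, 90.0, 90.0)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_volume(path) -> DensityVolume:
    import gemmi

    m = gemmi.read_ccp4_map(str(path))
    data = np.array(m.grid, copy=True).astype(np.float32)
    voxel = float(m.grid.spacing[0])
    return DensityVolume(data=data, voxel_size=voxel, meta={"path": str(path)})


def write_section_tiff(section: SectionImage, path) -> None:
    import tifffile

    tifffile.imwrite(
        str(path),
        section.data.astype(np.float32),
        resolution=(1e8 / section.pixel_size, 1e8 / section.pixel_size),
        metadata={
            "thickness_nm": section.thickness_nm,
            "offset_nm": section.offset_nm,
            "pixel_size_A": section.pixel_size,
        },
    )


def write_section_png(section: SectionImage, path) -> None:
    from PIL import Image

    lo, hi = np.percentile(section.data, [1, 99])
    scaled = np.clip((section.data - lo) / max(hi - lo, 1e-9), 0, 1)
    Image.fromarray((scaled * 255).astype(np.uint8)).save(str(path))


def write_records_csv(records, path) -> None:
    from .scenes import records_to_frame

    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    frame.to_csv(path, index=False)


def read_records_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_profile_csv(profile, path) -> None:
    pd.DataFrame({"radius_nm": profile.radii, "density": profile.density}).to_csv(
        path, index=False
    )


def read_profile_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_manifest(path, config: dict, seed: int, extra: dict | None = None) -> dict:
    """JSON run manifest: config, its hash, seed and package version."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": int(seed),
        "version": __version__,
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
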