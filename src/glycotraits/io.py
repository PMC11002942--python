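"""Delimited-text readers/writers and the machine-readable run log.

Spectra are two-column tab-delimited files (m/z, intensity) with ``#``-prefixed
provenance headers; cohorts carry a manifest table (file, group, bio, tech,
seed); peak, trait and comparison tables are plain TSV with header rows.
"""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .simulate import Cohort, SyntheticSpectrum

__all__ = [
    "write_spectrum",
    "read_spectrum",
    "write_cohort",
    "read_peak_list",
    "write_table",
    "read_table",
    "config_hash",
    "write_run_log",
]


def write_spectrum(spectrum: SyntheticSpectrum, path: "str | Path") -> None:
    path = Path(path)
    with path.open("w") as fh:
        for key, value in spectrum.meta.items():
            fh.write(f"# {key}: {value}\n")
        fh.write("# columns: mz\tintensity\n")
        np.savetxt(fh, np.column_stack([spectrum.mz, spectrum.intensity]),
                   fmt="%.5f\t%.6g")


def read_spectrum(path: "str | Path") -> SyntheticSpectrum:
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open() as fh:
        rows = []
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if ":" in body:
                    key, _, value = body.partition(":")
                    meta[key.strip()] = value.strip()
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"malformed spectrum line in {path}: {line!r}")
            rows.append((float(parts[0]), float(parts[1])))
    data = np.asarray(rows)
    return SyntheticSpectrum(data[:, 0], data[:, 1], meta)


def write_cohort(cohort: Cohort, outdir: "str | Path") -> Path:
    """Write every spectrum plus a manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = cohort.manifest.copy()
    files = []
    for idx, row in manifest.iterrows():
        name = f"{row['group']}_bio{row['bio']}_tech{row['tech']}.tsv"
        write_spectrum(cohort.spectra[idx], outdir / name)
        files.append(name)
    manifest.insert(0, "file", files)
    manifest_path = outdir / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)
    return manifest_path


def read_peak_list(path: "str | Path") -> pd.DataFrame:
    """Pre-picked peak list with at least m/z and area (S/N optional)."""
    table = pd.read_csv(path, sep="\t", comment="#")
    lower = {c.lower(): c for c in table.columns}
    if "mz" not in lower or not ({"area", "intensity"} & set(lower)):
        raise ValueError(
            f"peak list {path} must carry 'mz' and 'area' (or 'intensity') columns"
        )
    return table


def write_table(table: pd.DataFrame, path: "str | Path", index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=index)


def read_table(path: "str | Path") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def config_hash(config: Mapping) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_run_log(
    path: "str | Path",
    config: Mapping,
    seed: int,
    counts: Mapping[str, int],
) -> None:
    """Machine-readable provenance record for one pipeline run."""
    payload = {
        "config_hash": config_hash(config),
        "seed": int(seed),
        "python": sys.version.split()[0],
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "counts": dict(counts),
        "config": dict(config),
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
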