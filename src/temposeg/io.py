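"""Bank and manifest I/O.

Banks are stored as HDF5: one float32 dataset per stimulus under
``/stimuli/<spec key>/<variant>``, with the spec targets, seed, source and
convergence flag as dataset attributes, and the grid geometry plus a schema
version as file attributes.  A JSON manifest with the same metadata is
written alongside for tool-free inspection.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .grid import CorrelationSpec, GridSpec
from .stimulus import StimulusBank, StimulusTensor

__all__ = ["write_bank", "read_bank", "bank_manifest"]

SCHEMA_VERSION = 1


def bank_manifest(bank: StimulusBank) -> dict:
    """JSON-serializable summary of a bank's contents."""
    entries = []
    for key, variants in sorted(bank.stimuli.items()):
        spec = variants[0].spec
        entries.append(
            {
                "key": key,
                "xi_within": f"{spec.xi_within:g}",
                "xi_cross": f"{spec.xi_cross:g}",
                "is_null": spec.is_null,
                "n_variants": len(variants),
                "variants": [
                    {
                        "variant_id": s.variant_id,
                        "seed": s.seed,
                        "converged": s.converged,
                        "measured_within": s.measured_within,
                        "measured_cross": s.measured_cross,
                    }
                    for s in variants
                ],
            }
        )
    return {
        "schema_version": SCHEMA_VERSION,
        "source": bank.source,
        "seed": bank.seed,
        "grid": {
            "n_rows": bank.grid.n_rows,
            "n_cols": bank.grid.n_cols,
            "n_frames": bank.grid.n_frames,
            "frame_rate": bank.grid.frame_rate,
        },
        "n_stimuli": len(bank),
        "specs": entries,
    }


def write_bank(bank: StimulusBank, path: str | Path, manifest: bool = True) -> Path:
    """Write a bank (float32 payloads) and its JSON manifest sidecar."""
    path = Path(path)
    try:
        with h5py.File(path, "w") as fh:
            fh.attrs["schema_version"] = SCHEMA_VERSION
            fh.attrs["source"] = bank.source
            if bank.seed is not None:
                fh.attrs["seed"] = bank.seed
            for name, value in (
                ("n_rows", bank.grid.n_rows),
                ("n_cols", bank.grid.n_cols),
                ("n_frames", bank.grid.n_frames),
                ("frame_rate", bank.grid.frame_rate),
            ):
                fh.attrs[name] = value
            group = fh.create_group("stimuli")
            for key, variants in bank.stimuli.items():
                sub = group.create_group(key)
                for stim in variants:
                    ds = sub.create_dataset(
                        str(stim.variant_id), data=stim.values.astype(np.float32)
                    )
                    ds.attrs["xi_within"] = stim.spec.xi_within
                    ds.attrs["xi_cross"] = stim.spec.xi_cross
                    ds.attrs["is_null"] = stim.spec.is_null
                    ds.attrs["seed"] = stim.seed
                    ds.attrs["source"] = stim.source
                    if stim.converged is not None:
                        ds.attrs["converged"] = stim.converged
                    if stim.measured_within is not None:
                        ds.attrs["measured_within"] = stim.measured_within
                    if stim.measured_cross is not None:
                        ds.attrs["measured_cross"] = stim.measured_cross
    except OSError as exc:
        raise OSError(f"cannot write bank to {path}: {exc}") from exc
    if manifest:
        manifest_path = path.with_suffix(path.suffix + ".manifest.json")
        manifest_path.write_text(json.dumps(bank_manifest(bank), indent=2))
    return path


def read_bank(path: str | Path) -> StimulusBank:
    """Read a bank written by :func:`write_bank`; schema-checked."""
    path = Path(path)
    try:
        fh = h5py.File(path, "r")
    except OSError as exc:
        raise OSError(f"cannot open bank file {path}: {exc}") from exc
    with fh:
        version = int(fh.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"bank schema version {version} does not match supported {SCHEMA_VERSION}"
            )
        grid = GridSpec(
            n_rows=int(fh.attrs["n_rows"]),
            n_cols=int(fh.attrs["n_cols"]),
            n_frames=int(fh.attrs["n_frames"]),
            frame_rate=float(fh.attrs["frame_rate"]),
        )
        bank = StimulusBank(
            grid=grid,
            source=str(fh.attrs["source"]),
            seed=int(fh.attrs["seed"]) if "seed" in fh.attrs else None,
        )
        for key in fh["stimuli"]:
            sub = fh["stimuli"][key]
            for variant in sorted(sub, key=int):
                ds = sub[variant]
                spec = CorrelationSpec(
                    xi_within=float(ds.attrs["xi_within"]),
                    xi_cross=float(ds.attrs["xi_cross"]),
                    is_null=bool(ds.attrs["is_null"]),
                )
                stim = StimulusTensor(
                    values=np.asarray(ds, dtype=np.float64),
                    spec=spec,
                    seed=int(ds.attrs["seed"]),
                    source=str(ds.attrs["source"]),
                    variant_id=int(variant),
                    converged=bool(ds.attrs["converged"]) if "converged" in ds.attrs else None,
                    measured_within=float(ds.attrs["measured_within"])
                    if "measured_within" in ds.attrs
                    else None,
                    measured_cross=float(ds.attrs["measured_cross"])
                    if "measured_cross" in ds.attrs
                    else None,
                )
                bank.add(stim)
    return bank
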