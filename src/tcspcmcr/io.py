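"""Plain-text I/O for decay traces, IRFs and simulated datasets.

Traces are stored as two-column delimited text (time_ns, counts) with a
commented metadata header; a YAML manifest lists every file of a
simulated dataset.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .axes import DecayTrace, InstrumentResponse, TimeAxis

__all__ = [
    "write_decay_table",
    "read_decay_table",
    "write_dataset",
    "read_dataset",
    "ParseError",
]


class ParseError(ValueError):
    """Malformed decay-table file (message carries the line number)."""


def _header_lines(meta: dict) -> list[str]:
    lines = [f"# tcspcmcr {__version__}"]
    for k, v in meta.items():
        lines.append(f"# {k}: {v}")
    return lines


def write_decay_table(
    obj: DecayTrace | InstrumentResponse, path: str | Path, delimiter: str = "\t"
) -> Path:
    """Write a trace or IRF as commented-header two-column text."""
    path = Path(path)
    axis = obj.axis
    meta = {"bin_width_ns": axis.bin_width, "origin_ns": axis.origin,
            "n_bins": axis.n_bins}
    if isinstance(obj, InstrumentResponse):
        meta.update(kind="irf", fwhm_ns=obj.fwhm, t0_ns=obj.t0)
        counts = obj.counts
        fmt = "%.12g"
    else:
        meta.update(
            kind="decay",
            sequence_id=obj.sequence_id,
            ph=obj.ph,
            wavelength_nm=obj.wavelength,
        )
        counts = obj.counts
        fmt = "%d"
    with path.open("w") as fh:
        fh.write("\n".join(_header_lines(meta)) + "\n")
        fh.write(f"time_ns{delimiter}counts\n")
        for t, c in zip(axis.centers, counts):
            fh.write(f"{t:.9g}{delimiter}{fmt % c}\n")
    return path


def _parse_meta(lines: list[tuple[int, str]]) -> dict:
    meta = {}
    for _, line in lines:
        body = line.lstrip("#").strip()
        if ":" in body:
            key, _, val = body.partition(":")
            meta[key.strip()] = val.strip()
    return meta


def read_decay_table(path: str | Path) -> DecayTrace | InstrumentResponse:
    """Read a trace or IRF written by :func:`write_decay_table`.

    Raises :class:`ParseError` naming the offending line for malformed
    rows, non-monotone time columns or negative counts.
    """
    path = Path(path)
    header: list[tuple[int, str]] = []
    times: list[float] = []
    counts: list[float] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                header.append((lineno, line))
                continue
            parts = line.replace(",", "\t").split()
            if parts[0] == "time_ns":
                continue
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                t, c = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if c < 0:
                raise ParseError(f"{path}:{lineno}: negative counts {c}")
            times.append(t)
            counts.append(c)
    if not times:
        raise ParseError(f"{path}: no data rows (comment-only or empty body)")
    times_arr = np.array(times)
    if np.any(np.diff(times_arr) <= 0):
        bad = int(np.argmax(np.diff(times_arr) <= 0)) + 2
        raise ParseError(f"{path}: time column not strictly increasing near data row {bad}")
    meta = _parse_meta(header)
    bin_width = float(meta.get("bin_width_ns", times_arr[1] - times_arr[0]))
    origin = float(meta.get("origin_ns", times_arr[0] - bin_width / 2))
    axis = TimeAxis(n_bins=len(times), bin_width=bin_width, origin=origin)
    if meta.get("kind") == "irf":
        return InstrumentResponse(
            axis=axis,
            counts=np.array(counts),
            fwhm=float(meta.get("fwhm_ns", "nan")),
            t0=float(meta.get("t0_ns", "nan")),
        )
    return DecayTrace(
        axis=axis,
        counts=np.array(counts),
        sequence_id=meta.get("sequence_id", ""),
        ph=float(meta.get("ph", "nan")),
        wavelength=float(meta.get("wavelength_nm", "nan")),
    )


def write_dataset(
    traces: Sequence[DecayTrace],
    irf: InstrumentResponse,
    outdir: str | Path,
    seed: int | None = None,
) -> Path:
    """Write one IRF file, one file per trace and a YAML manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    irf_file = "irf.tsv"
    write_decay_table(irf, outdir / irf_file)
    entries = []
    for i, tr in enumerate(traces):
        name = f"trace_{i:03d}_{tr.sequence_id}_pH{tr.ph:g}_{tr.wavelength:g}nm.tsv"
        write_decay_table(tr, outdir / name)
        entries.append(
            {
                "file": name,
                "sequence_id": tr.sequence_id,
                "ph": float(tr.ph),
                "wavelength_nm": float(tr.wavelength),
            }
        )
    manifest = {
        "tool": f"tcspcmcr {__version__}",
        "seed": seed,
        "irf": irf_file,
        "traces": entries,
    }
    with (outdir / "manifest.yaml").open("w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return outdir / "manifest.yaml"


def read_dataset(outdir: str | Path) -> tuple[list[DecayTrace], InstrumentResponse]:
    """Load a dataset directory via its manifest."""
    outdir = Path(outdir)
    with (outdir / "manifest.yaml").open() as fh:
        manifest = yaml.safe_load(fh)
    irf_path = outdir / manifest["irf"]
    if not irf_path.exists():
        raise FileNotFoundError(f"IRF file missing: {irf_path}")
    irf = read_decay_table(irf_path)
    traces = [read_decay_table(outdir / e["file"]) for e in manifest["traces"]]
    return traces, irf
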