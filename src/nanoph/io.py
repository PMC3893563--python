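"""TIFF input, result output, and provenance records.

Input: 8/16-bit unsigned single- or multi-channel TIFFs (OME channel names
honored when present).  Output: 32-bit float pH maps (NaN = out-of-range
sentinel), RGB PNG colour maps, CSV histograms and summaries, and a sidecar
JSON carrying the full provenance (config, calibration, software version).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from . import __version__
from .calibration import CalibrationModel
from .pipeline import ChannelPair, PHField, WeightedHistogram

__all__ = [
    "read_channel_pair",
    "write_channel_pair",
    "write_results",
    "read_ph_map",
    "read_manifest",
]

_ALLOWED_DTYPES = (np.uint8, np.uint16)


def _check_dtype(arr: np.ndarray, path) -> np.ndarray:
    if arr.dtype not in [np.dtype(d) for d in _ALLOWED_DTYPES] and not np.issubdtype(
        arr.dtype, np.floating
    ):
        raise ValueError(
            f"{path}: unsupported bit depth {arr.dtype}; expected 8- or 16-bit unsigned"
        )
    return arr


def _resolve_channel(stack: np.ndarray, names: list[str] | None, key) -> np.ndarray:
    """Pick one channel plane from a (C, Y, X) stack by index or OME name."""
    if isinstance(key, str):
        if not names or key not in names:
            raise ValueError(f"channel name {key!r} not found; available: {names}")
        key = names.index(key)
    if not 0 <= key < stack.shape[0]:
        raise ValueError(f"channel index {key} out of range for {stack.shape[0]} channels")
    return stack[key]


def _ome_channel_names(tif: tifffile.TiffFile) -> list[str] | None:
    try:
        import xml.etree.ElementTree as ET

        root = ET.fromstring(tif.ome_metadata)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        names = [c.get("Name") for c in root.iter(f"{{{ns['ome']}}}Channel")]
        return names if any(names) else None
    except Exception:
        return None


def read_channel_pair(
    path,
    indicator=0,
    reference=1,
    reference_path=None,
    slice_index: int | None = None,
) -> ChannelPair:
    """Load an indicator/reference pair from one or two TIFF files.

    Single file: a multi-channel (or multi-page) TIFF; ``indicator`` and
    ``reference`` select planes by integer index or OME channel name.  Two
    files: each holds one single-channel image.  For z-stacks the analyst
    designates the most in-focus slice with ``slice_index``.
    """
    if reference_path is not None:
        ind = _check_dtype(tifffile.imread(path), path)
        ref = _check_dtype(tifffile.imread(reference_path), reference_path)
        if slice_index is not None:
            ind, ref = ind[slice_index], ref[slice_index]
    else:
        with tifffile.TiffFile(path) as tif:
            stack = _check_dtype(tif.asarray(), path)
            names = _ome_channel_names(tif) if tif.is_ome else None
        if slice_index is not None and stack.ndim == 4:  # (Z, C, Y, X)
            stack = stack[slice_index]
        if stack.ndim != 3:
            raise ValueError(
                f"{path}: expected a multi-channel image, got shape {stack.shape}"
            )
        ind = _resolve_channel(stack, names, indicator)
        ref = _resolve_channel(stack, names, reference)
    if ind.shape != ref.shape:
        raise ValueError(
            f"channel shapes differ: indicator {ind.shape} vs reference {ref.shape}; "
            "check the channel mapping and slice index"
        )
    return ChannelPair(indicator=ind.astype(float), reference=ref.astype(float))


def write_channel_pair(path, pair: ChannelPair, dtype=np.uint16) -> None:
    """Write a pair as a 2-channel TIFF (channels stacked on the first axis)."""
    stack = np.stack([pair.indicator, pair.reference]).astype(dtype)
    tifffile.imwrite(path, stack)


def read_ph_map(path) -> np.ndarray:
    return tifffile.imread(path)


def read_manifest(path) -> list[dict]:
    """Read a calibration manifest CSV: path,channel_indicator,channel_reference,ph."""
    import csv

    rows = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rows.append(
                {
                    "path": row["path"],
                    "channel_indicator": int(row.get("channel_indicator", 0)),
                    "channel_reference": int(row.get("channel_reference", 1)),
                    "ph": float(row["ph"]),
                }
            )
    return rows


def write_results(
    outdir,
    field: PHField | None = None,
    histogram: WeightedHistogram | None = None,
    summary: dict | None = None,
    colormap: np.ndarray | None = None,
    config: dict | None = None,
    model: CalibrationModel | None = None,
    prefix: str = "result",
) -> dict[str, Path]:
    """Emit the standard result files; returns the paths written.

    ph map → float32 TIFF (NaN sentinel); colour map → PNG; histogram and
    summary → CSV; provenance (config + calibration + version) → JSON.
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    errors = []

    def _emit(key, fn):
        try:
            p = fn()
            written[key] = p
        except Exception as exc:  # report per-file, keep writing the rest
            errors.append(f"{key}: {exc}")

    if field is not None:
        _emit(
            "ph_map",
            lambda: (
                tifffile.imwrite(outdir / f"{prefix}_ph.tif", field.to_image()),
                outdir / f"{prefix}_ph.tif",
            )[1],
        )
    if colormap is not None:
        def _png():
            import imageio.v3 as iio

            p = outdir / f"{prefix}_colormap.png"
            iio.imwrite(p, colormap)
            return p

        _emit("colormap", _png)
    if histogram is not None:
        def _hist():
            p = outdir / f"{prefix}_histogram.csv"
            df = pd.DataFrame(
                {
                    "bin_lo": histogram.edges[:-1],
                    "bin_hi": histogram.edges[1:],
                    "mass": histogram.masses,
                }
            )
            df.attrs = {}
            df.to_csv(p, index=False)
            # overflow bin appended as a labelled final row
            with open(p, "a") as fh:
                fh.write(f"out_of_range,,{histogram.out_of_range_mass}\n")
            return p

        _emit("histogram", _hist)
    if summary is not None:
        def _summ():
            p = outdir / f"{prefix}_summary.csv"
            pd.DataFrame([summary]).to_csv(p, index=False)
            return p

        _emit("summary", _summ)

    prov = {"software_version": __version__}
    if config is not None:
        prov["config"] = config
    if model is not None:
        prov["calibration"] = model.to_dict()
    if field is not None:
        prov["n_pixels"] = int(field.ph.size)
        prov["n_sentinel"] = int(field.sentinel_count)
    _emit(
        "provenance",
        lambda: (
            (outdir / f"{prefix}_provenance.json").write_text(json.dumps(prov, indent=2)),
            outdir / f"{prefix}_provenance.json",
        )[1],
    )

    if errors:
        raise IOError("some results could not be written: " + "; ".join(errors))
    return written


def read_histogram_csv(path) -> tuple[np.ndarray, np.ndarray, float]:
    """Reload a histogram CSV: (edges, masses, out_of_range_mass)."""
    import pandas as pd

    df = pd.read_csv(path)
    overflow = df[df["bin_lo"] == "out_of_range"]
    body = df[df["bin_lo"] != "out_of_range"]
    edges = np.concatenate(
        [body["bin_lo"].astype(float).to_numpy(), [float(body["bin_hi"].iloc[-1])]]
    )
    masses = body["mass"].astype(float).to_numpy()
    oor = float(overflow["mass"].iloc[0]) if len(overflow) else 0.0
    return edges, masses, oor
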