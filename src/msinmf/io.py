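"""Versioned on-disk formats with round-trip guarantees.

Text formats (diffable): stage tracks (TSV + metadata comments), scan
streams (indexed per-scan peak lists), serum tables and feature tables
(CSV).  The sparse cube container is the single binary artifact (NumPy
``.npz`` of COO triplets plus axis/pitch metadata).  Every container carries
a format version; mismatches are rejected naming both versions.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datacube import DataCube, MzAxis, build_mz_axis
from .phantom import ScanEvent, ScanStream, StageTrack

STAGE_TRACK_VERSION = 1
SCAN_STREAM_VERSION = 1
CUBE_VERSION = 1


class FormatVersionError(ValueError):
    pass


def _check_version(kind: str, found: int, expected: int) -> None:
    if int(found) != expected:
        raise FormatVersionError(
            f"{kind} container is version {found}, reader expects {expected}"
        )


# ---------------------------------------------------------------------------
# stage track
# ---------------------------------------------------------------------------

def write_stage_track(track: StageTrack, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# msinmf-stage-track v{STAGE_TRACK_VERSION}\n")
        fh.write(f"# velocity_x_um_s={track.velocity_x_um_s!r}\n")
        fh.write(f"# line_step_um={track.line_step_um!r}\n")
        for line, t0, t1 in track.pass_windows:
            fh.write(f"# pass {line} {t0!r} {t1!r}\n")
        fh.write("time_s\tx_um\ty_um\n")
        for t, x, y in track.samples:
            fh.write(f"{float(t)!r}\t{float(x)!r}\t{float(y)!r}\n")


def read_stage_track(path) -> StageTrack:
    path = Path(path)
    meta: dict[str, float] = {}
    windows = []
    rows = []
    header_seen = False
    with path.open() as fh:
        first = fh.readline().strip()
        if not first.startswith("# msinmf-stage-track v"):
            raise FormatVersionError(f"{path} is not a stage-track file")
        _check_version("stage-track", int(first.rsplit("v", 1)[1]), STAGE_TRACK_VERSION)
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("# pass "):
                _, _, idx, t0, t1 = line.split()
                windows.append((int(idx), float(t0), float(t1)))
            elif line.startswith("#"):
                key, value = line[1:].strip().split("=", 1)
                meta[key] = float(value)
            elif not header_seen:
                header_seen = True
            else:
                rows.append([float(v) for v in line.split("\t")])
    return StageTrack(
        samples=np.asarray(rows),
        velocity_x_um_s=meta["velocity_x_um_s"],
        line_step_um=meta["line_step_um"],
        pass_windows=tuple(windows),
    )


# ---------------------------------------------------------------------------
# scan stream
# ---------------------------------------------------------------------------

def write_scan_stream(stream: ScanStream, path) -> None:
    """Indexed text layout: one ``> time_s=<t>`` line per scan, then one
    ``<mz> <intensity>`` pair per peak (full float repr, round-trip exact)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# msinmf-scan-stream v{SCAN_STREAM_VERSION}\n")
        fh.write(f"# n_scans={len(stream)}\n")
        for scan in stream:
            fh.write(f"> time_s={float(scan.time_s)!r}\n")
            for m, i in zip(scan.mz, scan.intensity):
                fh.write(f"{float(m)!r} {float(i)!r}\n")


def read_scan_stream(path) -> ScanStream:
    path = Path(path)
    scans = []
    time_s = None
    mz: list[float] = []
    inten: list[float] = []

    def flush():
        if time_s is not None:
            scans.append(ScanEvent(time_s=time_s, mz=np.asarray(mz), intensity=np.asarray(inten)))

    with path.open() as fh:
        first = fh.readline().strip()
        if not first.startswith("# msinmf-scan-stream v"):
            raise FormatVersionError(f"{path} is not a scan-stream file")
        _check_version("scan-stream", int(first.rsplit("v", 1)[1]), SCAN_STREAM_VERSION)
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                time_s = float(line.split("=", 1)[1])
                mz, inten = [], []
            else:
                m, i = line.split()
                mz.append(float(m))
                inten.append(float(i))
        flush()
    return ScanStream(tuple(scans))


# ---------------------------------------------------------------------------
# cube container
# ---------------------------------------------------------------------------

def write_cube(cube: DataCube, path) -> None:
    coo = cube.values.tocoo()
    meta = dict(
        version=CUBE_VERSION,
        rows=cube.rows, cols=cube.cols, n_channels=cube.axis.n_channels,
        mz_lo=cube.axis.mz_lo, mz_hi=cube.axis.mz_hi,
        ref_mz=cube.axis.ref_mz, ref_bin_width=cube.axis.ref_bin_width,
        ref_sigma=cube.axis.ref_sigma,
        pixel_pitch_x_um=cube.pixel_pitch_x_um,
        pixel_pitch_y_um=cube.pixel_pitch_y_um,
    )
    np.savez(
        path,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        pixel=coo.row.astype(np.int64),
        channel=coo.col.astype(np.int64),
        value=coo.data.astype(np.float64),
    )


def read_cube(path) -> DataCube:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        _check_version("cube", meta["version"], CUBE_VERSION)
        axis = build_mz_axis(meta["mz_lo"], meta["mz_hi"], meta["ref_mz"],
                             meta["ref_bin_width"], meta["ref_sigma"])
        if meta["n_channels"] != axis.n_channels:
            # axis was truncated when the cube was built; honour the stored count
            axis = MzAxis(axis.mz_lo, axis.mz_hi, axis.ref_mz, axis.ref_bin_width,
                          axis.ref_sigma, axis.centers[: meta["n_channels"]])
        n_pixels = meta["rows"] * meta["cols"]
        values = sp.csr_matrix(
            (z["value"], (z["pixel"], z["channel"])),
            shape=(n_pixels, axis.n_channels),
        )
        return DataCube(
            values=values, rows=meta["rows"], cols=meta["cols"], axis=axis,
            pixel_pitch_x_um=meta["pixel_pitch_x_um"],
            pixel_pitch_y_um=meta["pixel_pitch_y_um"],
        )


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_serum_table(X: np.ndarray, labels: np.ndarray, feature_ids, path) -> None:
    df = pd.DataFrame(np.asarray(X), columns=list(feature_ids))
    df.insert(0, "class", labels)
    df.to_csv(path, index=False)


def read_serum_table(path, label_col: str = "class") -> tuple[np.ndarray, np.ndarray, list[str]]:
    df = pd.read_csv(path)
    labels = df[label_col].to_numpy()
    feats = [c for c in df.columns if c != label_col]
    return df[feats].to_numpy(dtype=float), labels, feats


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    from .annotation import load_reference_features

    return load_reference_features(path)
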