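"""Standard-format I/O: TIFF images, CSV tables, YAML reports."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .calibration import CalibrationCurve
from .fcs import IntensityTrace
from .frap import RecoveryTrace
from .segmentation import CellRecord, LabelMap, VesicleRecord


def write_channels_tiff(path, images: dict[str, np.ndarray]):
    """Multi-page TIFF, one page per channel (alphabetical); channel names in
    the page descriptions."""
    path = Path(path)
    names = sorted(images)
    with tifffile.TiffWriter(path) as tif:
        for name in names:
            tif.write(images[name], description=name)
    return names


def read_channels_tiff(path) -> dict[str, np.ndarray]:
    out = {}
    with tifffile.TiffFile(path) as tif:
        for i, page in enumerate(tif.pages):
            name = (page.description or f"channel_{i}").strip() or f"channel_{i}"
            out[name] = page.asarray()
    return out


def write_label_tiff(path, label_map: LabelMap):
    tifffile.imwrite(path, label_map.labels.astype(np.uint16))


def read_label_tiff(path, pixel_size: float = 1.0, kind: str = "nucleus") -> LabelMap:
    return LabelMap(tifffile.imread(path).astype(np.int32),
                    pixel_size=pixel_size, kind=kind)


def write_concentration_tiff(path, values: np.ndarray):
    tifffile.imwrite(path, np.asarray(values, dtype=np.float32))


def curve_to_yaml(curve: CalibrationCurve, path):
    data = asdict(curve)
    data["concentration_range"] = list(data["concentration_range"])
    Path(path).write_text(yaml.safe_dump(data))


def curve_from_yaml(path) -> CalibrationCurve:
    data = yaml.safe_load(Path(path).read_text())
    data["concentration_range"] = tuple(data["concentration_range"])
    return CalibrationCurve(**data)


def standards_from_csv(path) -> list[tuple[float, float]]:
    """Read calibration standards (concentration_molar, mean_counts)."""
    df = pd.read_csv(path)
    return list(zip(df["concentration_molar"], df["mean_counts"]))


def records_to_frame(records) -> pd.DataFrame:
    """Flatten Cell/Vesicle records to one row per object."""
    rows = []
    for r in records:
        row = {"object_id": r.object_id, "area_px": r.area,
               "equivalent_diameter_px": r.equivalent_diameter,
               "centroid_row": r.centroid[0], "centroid_col": r.centroid[1]}
        if isinstance(r, CellRecord):
            for ch, v in r.mean_intensity.items():
                row[f"mean_pct_{ch}"] = v
            row["injected"] = r.injected
        else:
            row["mean_concentration_molar"] = r.mean_concentration
            row["copies"] = r.copies
        rows.append(row)
    return pd.DataFrame(rows)


def records_from_frame(df: pd.DataFrame) -> list[CellRecord]:
    records = []
    chans = [c[len("mean_pct_"):] for c in df.columns if c.startswith("mean_pct_")]
    for _, row in df.iterrows():
        injected = row.get("injected")
        records.append(CellRecord(
            object_id=int(row["object_id"]), area=float(row["area_px"]),
            equivalent_diameter=float(row["equivalent_diameter_px"]),
            centroid=(float(row["centroid_row"]), float(row["centroid_col"])),
            mean_intensity={ch: float(row[f"mean_pct_{ch}"]) for ch in chans},
            injected=None if pd.isna(injected) else bool(injected)))
    return records


def trace_to_csv(trace: RecoveryTrace, path):
    pd.DataFrame({"time_s": trace.time, "roi_bleach": trace.roi_bleach,
                  "roi_reference": trace.roi_reference,
                  "roi_background": trace.roi_background}).to_csv(path, index=False)


def trace_from_csv(path, n_prebleach: int = 10,
                   bleach_radius: float = 2.0) -> RecoveryTrace:
    df = pd.read_csv(path)
    return RecoveryTrace(time=df["time_s"].to_numpy(),
                         roi_bleach=df["roi_bleach"].to_numpy(),
                         roi_reference=df["roi_reference"].to_numpy(),
                         roi_background=df["roi_background"].to_numpy(),
                         n_prebleach=n_prebleach, bleach_radius=bleach_radius)


def intensity_trace_to_csv(trace: IntensityTrace, path):
    with open(path, "w") as fh:
        fh.write(f"# bin_time_s={trace.bin_time}\ncounts\n")
        np.savetxt(fh, trace.counts, fmt="%d")


def intensity_trace_from_csv(path) -> IntensityTrace:
    with open(path) as fh:
        header = fh.readline()
    bin_time = float(header.split("=", 1)[1])
    counts = pd.read_csv(path, comment=None, skiprows=1)["counts"].to_numpy()
    return IntensityTrace(counts=counts, bin_time=bin_time)


def report_to_yaml(obj, path):
    """Serialize a dataclass report (FrapFit, FcsFit, ...) to YAML."""
    data = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in asdict(obj).items()}
    Path(path).write_text(yaml.safe_dump(data))
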