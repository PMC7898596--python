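"""Batch processing: one image through the whole pipeline, or a directory.

Per image: read -> grayscale -> polarity normalisation -> contrast
saturation -> HDM threshold -> multi-width ridge detection -> per-fibre
metrics on the chosen-width network -> global pattern metrics -> optional
gap analysis.  Artefacts written per image: fibre mask(s) (one per line
width plus the amalgam when sweeping), the HDM-thresholded image, and the
gap CSV.  A batch produces one summary CSV (one row per image, sorted by
filename), and a plain-text log that archives the parameter set, so every
run is reproducible from its own outputs.

Per-fibre metrics are computed on the detection pass at the minimum line
width (the amalgamated mask serves only the global pattern metrics);
floating-point columns are rounded to 6 significant digits at write time so
repeat runs are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gaps as gap_mod
from . import network_metrics as nm
from . import pattern_metrics as pm
from .image import GrayImage, read_image, write_gray
from .params import ParameterSet, save_parameters
from .preprocess import compute_hdm, contrast_saturate, normalise_polarity, to_grayscale
from .ridge import RidgeParams, detect_multiscale

__all__ = ["BatchResult", "process_image", "run_batch", "IMAGE_SUFFIXES"]

IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}


@dataclass
class BatchResult:
    records: list[nm.MetricsRecord] = field(default_factory=list)
    artefacts: dict = field(default_factory=dict)  # image_id -> list of paths
    failures: list[tuple[str, str]] = field(default_factory=list)
    summary_csv: Path | None = None
    log: Path | None = None


def _round_sig(x, digits: int = 6):
    if isinstance(x, float) and np.isfinite(x) and x != 0:
        return float(f"{x:.{digits}g}")
    return x


def records_to_frame(records: list[nm.MetricsRecord]) -> pd.DataFrame:
    rows = [r.as_row() for r in records]
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values("image_id").reset_index(drop=True)
        for col in df.columns:
            if df[col].dtype == float:
                df[col] = df[col].map(_round_sig)
    return df


def _versioned(path: Path) -> None:
    """Move an existing file aside (file.ext -> file.ext.1, .2, ...)."""
    if not path.exists():
        return
    n = 1
    while (cand := path.with_name(path.name + f".{n}")).exists():
        n += 1
    path.rename(cand)


def process_array(
    raw: np.ndarray | GrayImage,
    params: ParameterSet,
    image_id: str = "image",
    output_dir: Path | None = None,
) -> tuple[nm.MetricsRecord, list[Path]]:
    """Run the full metric pipeline on an in-memory image.

    Returns the metrics record and the list of artefact paths written
    (empty when ``output_dir`` is None).
    """
    if isinstance(raw, GrayImage):
        gray = raw
    else:
        gray = to_grayscale(raw, pixel_size_um=params.pixel_size_um)
    if params.pixel_size_um is not None:
        gray.pixel_size_um = params.pixel_size_um
    gray = normalise_polarity(gray, params.dark_lines)
    gray = contrast_saturate(gray, params.contrast_saturation_pct)
    hdm_fraction, hdm_mask = compute_hdm(gray, params.hdm_threshold)

    ridge_params = RidgeParams(
        line_width_min_px=params.line_width_min_px,
        line_width_max_px=params.line_width_max_px,
        contrast_high=params.contrast_high,
        contrast_low=params.contrast_low,
        min_branch_px=params.min_branch_px,
        dark_lines=False,  # polarity already normalised
    )
    amalgam, networks = detect_multiscale(gray, ridge_params)
    net = networks[0]  # metrics at the minimum line width

    rec = nm.network_record(
        net,
        image_id=image_id,
        hdm_fraction=hdm_fraction,
        curvature_windows=(
            params.curvature_window_min_px,
            params.curvature_window_max_px,
            params.curvature_window_step_px,
        ),
    )
    rec.alignment = pm.alignment_from_image(gray)
    rec.fractal_dim = pm.fractal_dimension(amalgam)
    rec.lacunarity = pm.lacunarity(amalgam)

    gap_rows = None
    if params.gap_analysis:
        circles = gap_mod.max_inscribed_circles(amalgam, params.min_gap_diameter_px)
        rec.gap_stats = gap_mod.gap_statistics(circles)
        gap_rows = gap_mod.circles_to_rows(circles)

    paths: list[Path] = []
    if output_dir is not None:
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        stem = Path(image_id).stem
        widths = ridge_params.widths()
        for w, wnet in zip(widths, networks):
            from .ridge import rasterize

            p = output_dir / f"{stem}_mask_w{w:g}.png"
            _versioned(p)
            write_gray(p, rasterize(wnet))
            paths.append(p)
        if len(widths) > 1:
            p = output_dir / f"{stem}_mask_amalgam.png"
            _versioned(p)
            write_gray(p, amalgam)
            paths.append(p)
        p = output_dir / f"{stem}_hdm.png"
        _versioned(p)
        write_gray(p, hdm_mask)
        paths.append(p)
        if gap_rows is not None:
            p = output_dir / f"{stem}_gaps.csv"
            _versioned(p)
            pd.DataFrame(
                gap_rows, columns=["circle_id", "row", "col", "radius_px", "area_px2"]
            ).to_csv(p, index=False)
            paths.append(p)
    return rec, paths


def process_image(
    img_path: str | Path, params: ParameterSet, output_dir: Path | None = None
) -> tuple[nm.MetricsRecord, list[Path]]:
    """Read one image file and run the full pipeline on it."""
    img_path = Path(img_path)
    raw = read_image(img_path)
    return process_array(raw, params, image_id=img_path.name, output_dir=output_dir)


def run_batch(
    input_dir: str | Path, params: ParameterSet, output_dir: str | Path
) -> BatchResult:
    """Process every eligible image in a directory.

    Unreadable or corrupt images are logged and skipped; the batch
    continues.  Raises when the directory holds no eligible image at all.
    """
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    files = sorted(
        p for p in input_dir.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES and p.is_file()
    )
    if not files:
        raise FileNotFoundError(f"no eligible images (png/tif/jpg) in {input_dir}")
    output_dir.mkdir(parents=True, exist_ok=True)

    result = BatchResult()
    log_lines = [f"fibremetrics batch: {len(files)} candidate image(s) from {input_dir}"]
    for f in files:
        try:
            rec, paths = process_image(f, params, output_dir=output_dir)
        except Exception as exc:  # noqa: BLE001 — batch must continue
            result.failures.append((f.name, str(exc)))
            log_lines.append(f"FAILED {f.name}: {exc}")
            continue
        result.records.append(rec)
        result.artefacts[f.name] = paths
        log_lines.append(f"ok     {f.name}")

    df = records_to_frame(result.records)
    summary = output_dir / "summary.csv"
    _versioned(summary)
    header = (
        f"# fibremetrics summary; norm_length is total length per "
        f"{nm.NORM_LENGTH_SCALE:g} px^2 of image; missing values are empty cells\n"
    )
    with open(summary, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)
    result.summary_csv = summary

    log = output_dir / "run.log"
    _versioned(log)
    params_path = output_dir / "parameters.txt"
    _versioned(params_path)
    save_parameters(params, params_path)
    log_lines.append(f"parameters archived to {params_path.name}")
    log_lines.append(f"{len(result.records)} processed, {len(result.failures)} failed")
    log.write_text("\n".join(log_lines) + "\n")
    result.log = log
    return result
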