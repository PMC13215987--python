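"""End-to-end orchestration: slice -> preprocess -> segment -> delineate ->
quantify -> evaluate, for one or more segmentation backends.

A :class:`RunConfig` describes one case (a phantom spec or image paths),
the methods to run, the preprocessing configuration and the acquisition
geometry.  :func:`run_case` writes, per method, the preprocessed image,
the adipose/SAT/VAT masks, a surfaces table and (when reference masks are
available) an evaluation table, plus a machine-readable manifest holding
the config, the seed and package versions.  Identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from . import __version__, image_io
from .anatomy import apply_abdominal_mask, build_abdominal_mask, delineate_vat_sat
from .metrics import EvalReport, evaluate_compartments
from .phantom import CompartmentMasks, PhantomSpec, generate_slice_phantom
from .preprocess import PreprocessConfig, preprocess_slice
from .quantify import PixelGeometry, SurfaceReport, distribution_indices, surface
from .segment import SegmentationConfig, segment

logger = logging.getLogger(__name__)

METHODS = ("otsu", "kmeans", "fcm")


@dataclass(frozen=True)
class RunConfig:
    """One case of the automated pipeline."""

    out_dir: str
    methods: tuple[str, ...] = ("otsu",)
    seed: int = 0
    phantom: PhantomSpec | None = None
    image_path: str | None = None
    ref_sat_path: str | None = None
    ref_vat_path: str | None = None
    abdominal_mask_path: str | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    geometry: PixelGeometry | None = None
    case_id: str = "case"

    def validate(self) -> None:
        if not self.methods:
            raise ValueError("at least one segmentation method is required")
        bad = set(self.methods) - set(METHODS)
        if bad:
            raise ValueError(f"unknown methods {sorted(bad)}")
        if (self.phantom is None) == (self.image_path is None):
            raise ValueError("provide exactly one of phantom spec or image path")


@dataclass
class CaseResult:
    method: str
    surfaces: SurfaceReport
    evaluation: EvalReport | None
    masks: CompartmentMasks


def _load_case(cfg: RunConfig):
    """Resolve the input image, reference masks, and abdominal mask."""
    if cfg.phantom is not None:
        spec = dataclasses.replace(cfg.phantom, seed=cfg.seed)
        img, truth, _arms, abdominal = generate_slice_phantom(spec)
        ref = {"sat": truth.sat, "vat": truth.vat, "tat": truth.tat}
        return img, ref, abdominal
    img = image_io.read_image(cfg.image_path)
    ref = None
    if cfg.ref_sat_path and cfg.ref_vat_path:
        sat = image_io.read_mask(cfg.ref_sat_path)
        vat = image_io.read_mask(cfg.ref_vat_path)
        ref = {"sat": sat, "vat": vat, "tat": ((sat | vat) > 0).astype(np.uint8)}
    if cfg.abdominal_mask_path:
        abdominal = image_io.read_mask(cfg.abdominal_mask_path)
    else:
        abdominal = build_abdominal_mask(img)
    return img, ref, abdominal


def run_case(cfg: RunConfig) -> dict[str, CaseResult]:
    """Run every configured method on one case and write all artifacts."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img, ref, abdominal = _load_case(cfg)
    pre = preprocess_slice(img, cfg.preprocess)
    image_io.write_image(pre, out / f"{cfg.case_id}_preprocessed.tif")
    image_io.write_mask(abdominal, out / f"{cfg.case_id}_abdominal.png")

    geom = cfg.geometry or PixelGeometry(
        fov_row_mm=float(img.shape[0]),
        fov_col_mm=float(img.shape[1]),
        n_rows=img.shape[0],
        n_cols=img.shape[1],
    )

    results: dict[str, CaseResult] = {}
    surface_rows = []
    eval_rows = []
    for method in cfg.methods:
        seg_cfg = SegmentationConfig(method=method, seed=cfg.seed)
        seg = segment(pre, seg_cfg)
        adipose = apply_abdominal_mask(seg.mask, abdominal)
        comps = delineate_vat_sat(adipose)
        for name, m in (("adipose", adipose), ("sat", comps.sat), ("vat", comps.vat)):
            image_io.write_mask(m, out / f"{cfg.case_id}_{method}_{name}.png")
        sat_cm2 = surface(comps.sat, geom)
        vat_cm2 = surface(comps.vat, geom)
        report = distribution_indices(sat_cm2, vat_cm2)
        surface_rows.append(
            {
                "case": cfg.case_id,
                "method": method,
                "sat_cm2": report.sat_cm2,
                "vat_cm2": report.vat_cm2,
                "tat_cm2": report.tat_cm2,
                "vat_tat_pct": report.vat_tat_pct,
                "vat_sat_ratio": report.vat_sat_ratio,
            }
        )
        evaluation = None
        if ref is not None:
            pred = {"sat": comps.sat, "vat": comps.vat, "tat": comps.tat}
            evaluation = evaluate_compartments(pred, ref, method, cfg.case_id)
            for tissue, score in evaluation.scores.items():
                eval_rows.append(
                    {
                        "case": cfg.case_id,
                        "method": method,
                        "compartment": tissue,
                        "dice": score.dice,
                        "hausdorff_px": score.hausdorff_px,
                        "tp": score.confusion.tp,
                        "fp": score.confusion.fp,
                        "fn": score.confusion.fn,
                        "tn": score.confusion.tn,
                    }
                )
        results[method] = CaseResult(method, report, evaluation, comps)

    pd.DataFrame(surface_rows).to_csv(out / "surfaces.csv", index=False)
    if eval_rows:
        pd.DataFrame(eval_rows).to_csv(out / "evaluation.csv", index=False)

    manifest = {
        "slicefat_version": __version__,
        "seed": cfg.seed,
        "case_id": cfg.case_id,
        "methods": list(cfg.methods),
        "preprocess": dataclasses.asdict(cfg.preprocess),
        "phantom": dataclasses.asdict(cfg.phantom) if cfg.phantom else None,
        "image_path": cfg.image_path,
        "geometry": dataclasses.asdict(geom),
        "surfaces": surface_rows,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return results


def run_batch(configs: list[RunConfig]) -> dict[str, dict[str, CaseResult]]:
    """Run many cases; a failure in one case is logged and does not stop
    the rest."""
    out: dict[str, dict[str, CaseResult]] = {}
    for cfg in configs:
        try:
            out[cfg.case_id] = run_case(cfg)
        except Exception:
            logger.exception("case %s failed; continuing batch", cfg.case_id)
    return out


def compare_methods(reports: list[EvalReport]) -> pd.DataFrame:
    """Paired method comparison across a common case set.

    Returns one row per (method, compartment) with mean/SD Dice and
    Hausdorff, plus the paired Wilcoxon signed-rank p-value of each
    method's Dice against the first method (identical scores give p = 1 by
    convention).  Requires every method to cover the same cases.
    """
    rows = [
        {
            "method": r.method,
            "case": r.case_id,
            "compartment": t,
            "dice": s.dice,
            "hausdorff_px": s.hausdorff_px,
        }
        for r in reports
        for t, s in r.scores.items()
    ]
    df = pd.DataFrame(rows)
    methods = list(dict.fromkeys(df["method"]))
    if len(methods) < 2:
        raise ValueError("need at least two methods to compare")
    case_sets = {m: set(df[df["method"] == m]["case"]) for m in methods}
    if len({frozenset(v) for v in case_sets.values()}) != 1:
        raise ValueError("methods were not evaluated on identical case sets")

    baseline = methods[0]
    out_rows = []
    for method in methods:
        for tissue, grp in df[df["method"] == method].groupby("compartment"):
            grp = grp.sort_values("case")
            base = df[(df["method"] == baseline) & (df["compartment"] == tissue)]
            base = base.sort_values("case")
            diffs = grp["dice"].to_numpy() - base["dice"].to_numpy()
            if method == baseline or np.allclose(diffs, 0):
                p = 1.0
            else:
                p = float(wilcoxon(diffs).pvalue)
            out_rows.append(
                {
                    "method": method,
                    "compartment": tissue,
                    "dice_mean": float(grp["dice"].mean()),
                    "dice_sd": float(grp["dice"].std(ddof=1)),
                    "hausdorff_mean": float(grp["hausdorff_px"].mean()),
                    "hausdorff_sd": float(grp["hausdorff_px"].std(ddof=1)),
                    "wilcoxon_p_vs_" + baseline: p,
                }
            )
    return pd.DataFrame(out_rows)
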