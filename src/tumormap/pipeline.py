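"""Configured, logged pipeline: simulate → segment → profile → test → report.

A single TOML config file is the source of truth for a run; every threshold
and the seed are echoed into the outputs so each analysis is reproducible
from its manifest alone. Outputs land under ``<out>/images``, ``<out>/truth``,
``<out>/masks``, ``<out>/tables`` and ``<out>/figures``, with one JSON
manifest per stage listing every emitted file with its SHA-256 checksum.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .image_io import (
    read_roi_set,
    read_section,
    write_channel,
    write_roi_set,
    write_section,
)
from .metrics import (
    correlate_density_expression,
    heatmap,
    intensity_histogram,
    profile_lesions,
    profiles_to_frame,
)
from .segmentation import (
    RoiSet,
    apply_manual_rois,
    detect_cd31_objects,
    mask_nuclei,
    propose_lesions,
)
from .stats import SampleGroup, boxplot_summary, kruskal_wallis, subsample_pixels
from .synthetic import generate_tumor_map, spec_from_dict
from .types import (
    CHANNEL_CD31,
    CHANNEL_HOECHST,
    ConfigError,
    DEFAULT_PIXEL_SIZE,
    TumorMapError,
)

__all__ = ["PipelineConfig", "RunManifest", "run_simulate", "run_analyze",
           "run_report", "run_all", "verify_manifest"]

log = logging.getLogger(__name__)

# fixed palette for heat-map PNGs: background black, weak blue,
# moderate yellow, strong red
_HEAT_PALETTE = [(0, 0, 0), (40, 70, 220), (235, 200, 40), (210, 30, 30)]


@dataclass
class AnalyzeConfig:
    channels: dict[str, str] = field(default_factory=dict)  # name → TIFF path
    roi_source: str = "auto"  # auto | truth | path to a manual label TIFF
    manual_roi: str = ""  # optional manual override on top of auto proposals
    align: bool = False
    reference_channel: str = CHANNEL_HOECHST
    max_shift: int = 20
    nuclei_threshold: object = "auto"
    cd31_threshold: object = "auto"
    min_object_px: int = 4
    min_lesion_px: int = 500
    closing_radius: int = 10
    heat_channel: str = "her2"
    heat_edges: tuple[int, int] = (85, 170)
    n_max: int = 10_000


@dataclass
class ReportConfig:
    markers: list[str] = field(default_factory=list)
    dpi: int = 100


@dataclass
class PipelineConfig:
    """Everything one run needs, parsed from a single TOML file."""

    seed: int
    out_dir: Path
    section_id: str = "section"
    organ: str = ""
    pixel_size: float = DEFAULT_PIXEL_SIZE
    synthetic: dict | None = None
    analyze: AnalyzeConfig = field(default_factory=AnalyzeConfig)
    report: ReportConfig = field(default_factory=ReportConfig)

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        path = Path(path)
        try:
            raw = tomllib.loads(path.read_text())
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"{path}: not valid TOML: {exc}") from exc
        return cls.from_dict(raw, base_dir=path.parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path = Path(".")) -> "PipelineConfig":
        run = raw.get("run", {})
        if "seed" not in run or "out_dir" not in run:
            raise ConfigError("config [run] section must set 'seed' and 'out_dir'")
        ana_raw = dict(raw.get("analyze", {}))
        channels = {k: str(v) for k, v in ana_raw.pop("channels", {}).items()}
        known = {f.name for f in dataclasses.fields(AnalyzeConfig)}
        unknown = set(ana_raw) - known
        if unknown:
            raise ConfigError(f"unknown [analyze] keys: {sorted(unknown)}")
        if "heat_edges" in ana_raw:
            ana_raw["heat_edges"] = tuple(int(v) for v in ana_raw["heat_edges"])
        ana = AnalyzeConfig(channels=channels, **ana_raw)
        rep_raw = raw.get("report", {})
        rep = ReportConfig(
            markers=[str(m) for m in rep_raw.get("markers", [])],
            dpi=int(rep_raw.get("dpi", 100)),
        )
        out_dir = Path(run["out_dir"])
        if not out_dir.is_absolute():
            out_dir = base_dir / out_dir
        return cls(
            seed=int(run["seed"]),
            out_dir=out_dir,
            section_id=str(run.get("section_id", "section")),
            organ=str(run.get("organ", "")),
            pixel_size=float(run.get("pixel_size", DEFAULT_PIXEL_SIZE)),
            synthetic=raw.get("synthetic"),
            analyze=ana,
            report=rep,
        )

    def header(self) -> str:
        return (f"section={self.section_id} seed={self.seed} "
                f"tumormap={__version__}")

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        return d


@dataclass
class RunManifest:
    """Inventory of one pipeline stage: config, timings, warnings, files."""

    stage: str
    seed: int
    version: str
    config: dict
    timings_s: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    files: dict[str, str] = field(default_factory=dict)  # rel path → sha256

    def add_file(self, out_dir: Path, path: Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.files[str(Path(path).relative_to(out_dir))] = digest

    def write(self, out_dir: Path) -> Path:
        path = Path(out_dir) / f"manifest_{self.stage}.json"
        payload = dataclasses.asdict(self)
        path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
        return path


def verify_manifest(out_dir, stage: str) -> list[str]:
    """Recompute checksums for a stage's manifest; return the problems found."""
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / f"manifest_{stage}.json").read_text())
    problems = []
    for rel, digest in manifest["files"].items():
        p = out_dir / rel
        if not p.exists():
            problems.append(f"missing: {rel}")
        elif hashlib.sha256(p.read_bytes()).hexdigest() != digest:
            problems.append(f"checksum mismatch: {rel}")
    return problems


def _timed(timings: dict, name: str, fn, *args, **kw):
    t0 = time.perf_counter()
    result = fn(*args, **kw)
    timings[name] = round(time.perf_counter() - t0, 4)
    return result


def run_simulate(cfg: PipelineConfig) -> RunManifest:
    """Render the configured synthetic section; write channels + ground truth."""
    if cfg.synthetic is None:
        raise ConfigError("config has no [synthetic] section; nothing to simulate")
    man = RunManifest("simulate", cfg.seed, __version__, cfg.snapshot())
    syn = dict(cfg.synthetic)
    syn.setdefault("seed", cfg.seed)
    syn.setdefault("section_id", cfg.section_id)
    syn.setdefault("organ", cfg.organ)
    syn.setdefault("pixel_size", cfg.pixel_size)
    spec = spec_from_dict(syn)
    tm, gt = _timed(man.timings_s, "generate", generate_tumor_map, spec)

    out = cfg.out_dir
    img_dir = out / "images"
    truth_dir = out / "truth"
    for path in write_section(tm, img_dir).values():
        man.add_file(out, path)

    truth_table = gt.lesion_table.assign(kind="lesion")
    rois = RoiSet(
        gt.roi_labels,
        pd.DataFrame({
            "id": truth_table["lesion_id"].astype(int),
            "kind": "lesion",
            "organ": truth_table["organ"],
            "area_px": truth_table["area_px"].astype(int),
        }),
    )
    roi_tif = truth_dir / f"{cfg.section_id}_roi_truth.tif"
    roi_csv = truth_dir / f"{cfg.section_id}_roi_truth.csv"
    write_roi_set(rois, roi_tif, roi_csv)
    lesion_csv = truth_dir / f"{cfg.section_id}_lesions_truth.csv"
    truth_dir.mkdir(parents=True, exist_ok=True)
    with open(lesion_csv, "w") as fh:
        fh.write(f"# {cfg.header()}\n")
        gt.lesion_table.to_csv(fh, index=False)
    vessel_csv = truth_dir / f"{cfg.section_id}_vessels_truth.csv"
    pd.DataFrame(gt.vessel_centers, columns=["row", "col"]).to_csv(
        vessel_csv, index=False
    )
    for p in (roi_tif, roi_csv, lesion_csv, vessel_csv):
        man.add_file(out, p)
    man.write(out)
    return man


def _empty_tables(cfg: PipelineConfig, man: RunManifest) -> None:
    tables = cfg.out_dir / "tables"
    tables.mkdir(parents=True, exist_ok=True)
    for name, cols in [
        ("profiles.csv", ["roi_id", "organ"]),
        ("stats.csv", ["section", "grouping", "channel", "k", "N", "H", "df", "p", "flags"]),
    ]:
        p = tables / name
        with open(p, "w") as fh:
            fh.write(f"# {cfg.header()}\n")
            pd.DataFrame(columns=cols).to_csv(fh, index=False)
        man.add_file(cfg.out_dir, p)


def _load_rois(cfg: PipelineConfig, nuclei, man: RunManifest) -> RoiSet:
    a = cfg.analyze
    if a.roi_source == "truth":
        truth_dir = cfg.out_dir / "truth"
        rois = read_roi_set(
            truth_dir / f"{cfg.section_id}_roi_truth.tif",
            truth_dir / f"{cfg.section_id}_roi_truth.csv",
        )
    elif a.roi_source == "auto":
        rois = propose_lesions(nuclei, a.min_lesion_px, a.closing_radius)
        if a.manual_roi:
            import tifffile

            stored = tifffile.imread(a.manual_roi).astype(np.int64)
            stored[stored == 65535] = -1
            rois = apply_manual_rois(rois, stored.astype(np.int32))
            man.warnings.append(f"manual ROI override applied from {a.manual_roi}")
    else:
        # roi_source is a path to a label TIFF used as-is
        import tifffile

        stored = tifffile.imread(a.roi_source).astype(np.int64)
        stored[stored == 65535] = -1
        labels = stored.astype(np.int32)
        ids = sorted(np.unique(labels[labels > 0]).tolist())
        table = pd.DataFrame({
            "id": ids, "kind": "lesion", "organ": cfg.organ,
            "area_px": [int((labels == i).sum()) for i in ids],
        })
        rois = RoiSet(labels, table)
    if cfg.organ:
        tab = rois.table.copy()
        tab.loc[tab["organ"].astype(str) == "", "organ"] = cfg.organ
        rois = RoiSet(rois.labels, tab)
    return rois


def _subsample_seed(seed: int, roi_id: int, channel_index: int) -> int:
    # distinct, reproducible stream per (lesion, channel); stays below 2**31
    return (seed * 1_000_003 + roi_id * 101 + channel_index) % (2**31)


def run_analyze(cfg: PipelineConfig) -> RunManifest:
    """Segment, profile and test one section; write tables, masks, heat maps."""
    man = RunManifest("analyze", cfg.seed, __version__, cfg.snapshot())
    out = cfg.out_dir
    a = cfg.analyze

    if a.channels:
        paths = {name: Path(p) for name, p in a.channels.items()}
    else:
        img_dir = out / "images"
        paths = {
            p.stem.removeprefix(f"{cfg.section_id}_"): p
            for p in sorted(img_dir.glob(f"{cfg.section_id}_*.tif"))
        }
    if not paths:
        raise ConfigError("no input channels: set [analyze].channels or run simulate")
    tm = _timed(man.timings_s, "read", read_section, paths, cfg.pixel_size, cfg.section_id)
    if CHANNEL_HOECHST not in tm or CHANNEL_CD31 not in tm:
        raise ConfigError(
            f"analysis needs 'hoechst' and 'cd31' channels, got {sorted(tm.channels)}"
        )

    if a.align:
        from .image_io import align_channels

        tm, rep = _timed(
            man.timings_s, "align", align_channels,
            list(tm.channels.values()), a.reference_channel, a.max_shift,
        )
        for ch, fl in rep.flags.items():
            for f in fl:
                man.warnings.append(f"align {ch}: {f}")

    def _safe_mask(fn, channel, threshold, name):
        # crash-free on degenerate fixtures: a constant channel has no
        # detectable objects, so auto-thresholding falls back to an empty mask
        try:
            return fn(channel, threshold, a.min_object_px)
        except TumorMapError as exc:
            if "degenerate histogram" not in str(exc):
                raise
            man.warnings.append(f"{name}: {exc}; using empty mask")
            from .segmentation import BinaryMask

            empty = BinaryMask(
                np.zeros(channel.shape, bool), channel.channel, 255, a.min_object_px
            )
            return (empty, 0) if fn is detect_cd31_objects else empty

    nuclei = _timed(man.timings_s, "mask_nuclei", _safe_mask,
                    mask_nuclei, tm[CHANNEL_HOECHST], a.nuclei_threshold, "nuclei")
    cd31_mask, n_objects = _timed(man.timings_s, "detect_cd31", _safe_mask,
                                  detect_cd31_objects, tm[CHANNEL_CD31],
                                  a.cd31_threshold, "cd31")
    rois = _timed(man.timings_s, "rois", _load_rois, cfg, nuclei, man)

    masks_dir = out / "masks"
    import tifffile

    masks_dir.mkdir(parents=True, exist_ok=True)
    for name, arr in [("nuclei_mask", nuclei.pixels), ("cd31_mask", cd31_mask.pixels)]:
        p = masks_dir / f"{cfg.section_id}_{name}.tif"
        tifffile.imwrite(p, arr.astype(np.uint8) * 255, photometric="minisblack")
        man.add_file(out, p)
    roi_tif = masks_dir / f"{cfg.section_id}_roi.tif"
    roi_csv = masks_dir / f"{cfg.section_id}_roi.csv"
    write_roi_set(rois, roi_tif, roi_csv)
    man.add_file(out, roi_tif)
    man.add_file(out, roi_csv)

    lesion_ids = sorted(rois.lesion_ids)
    if not lesion_ids:
        man.warnings.append("no lesions found; emitting empty tables")
        _empty_tables(cfg, man)
        man.write(out)
        return man

    profiles = _timed(man.timings_s, "profiles", profile_lesions,
                      tm, rois, nuclei, cd31_mask)
    tables = out / "tables"
    tables.mkdir(parents=True, exist_ok=True)
    pframe = profiles_to_frame(profiles)
    pframe.insert(0, "section", cfg.section_id)
    p = tables / "profiles.csv"
    with open(p, "w") as fh:
        fh.write(f"# {cfg.header()} cd31_threshold={cd31_mask.threshold_used} "
                 f"nuclei_threshold={nuclei.threshold_used} n_objects={n_objects}\n")
        pframe.to_csv(fh, index=False)
    man.add_file(out, p)

    marker_channels = [c for c in sorted(tm.channels)
                       if c not in (CHANNEL_HOECHST, CHANNEL_CD31)]
    channel_order = sorted(tm.channels)

    # per-channel histograms: 256 rows × one column per lesion
    t0 = time.perf_counter()
    hists: dict[str, dict[int, object]] = {}
    for ch in channel_order:
        cols = {"intensity": np.arange(256)}
        hists[ch] = {}
        for rid in lesion_ids:
            h = intensity_histogram(tm[ch], rois, rid)
            hists[ch][rid] = h
            cols[f"roi_{rid}"] = h.bins
        p = tables / f"histograms_{ch}.csv"
        with open(p, "w") as fh:
            fh.write(f"# {cfg.header()} channel={ch} units=percent_of_roi_pixels\n")
            pd.DataFrame(cols).to_csv(fh, index=False)
        man.add_file(out, p)
    man.timings_s["histograms"] = round(time.perf_counter() - t0, 4)

    # heat map for the configured marker channel
    if a.heat_channel in tm:
        hm = heatmap(tm[a.heat_channel], rois, a.heat_edges)
        p = masks_dir / f"{cfg.section_id}_heatmap_{a.heat_channel}.tif"
        tifffile.imwrite(p, hm.classes, photometric="minisblack")
        man.add_file(out, p)
        from PIL import Image

        pal = Image.fromarray(hm.classes, mode="P")
        flat = [v for rgb in _HEAT_PALETTE for v in rgb]
        pal.putpalette(flat + [0] * (768 - len(flat)))
        fig_dir = out / "figures"
        fig_dir.mkdir(parents=True, exist_ok=True)
        png = fig_dir / f"{cfg.section_id}_heatmap_{a.heat_channel}.png"
        pal.save(png)
        man.add_file(out, png)
    else:
        man.warnings.append(
            f"heat-map channel {a.heat_channel!r} not in section; skipped"
        )

    # Kruskal–Wallis on subsampled per-lesion pixel intensities, per marker
    t0 = time.perf_counter()
    stats_rows = []
    for ch in marker_channels:
        groups = [
            subsample_pixels(
                hists[ch][rid], a.n_max,
                seed=_subsample_seed(cfg.seed, rid, channel_order.index(ch)),
                group_id=rid,
            )
            for rid in lesion_ids
        ]
        bp = boxplot_summary(groups)
        p = tables / f"boxplot_{ch}.csv"
        with open(p, "w") as fh:
            fh.write(f"# {cfg.header()} channel={ch} n_max={a.n_max}\n")
            bp.to_csv(fh, index=False)
        man.add_file(out, p)
        if len(groups) >= 2:
            kw = kruskal_wallis(groups)
            stats_rows.append({
                "section": cfg.section_id, "grouping": "lesion_pixels",
                "channel": ch, "k": kw.k, "N": kw.n_total, "H": kw.H,
                "df": kw.df, "p": kw.p, "flags": ";".join(kw.flags),
            })
        else:
            man.warnings.append(f"{ch}: single lesion, KW skipped")

    # KW on per-lesion vascular densities grouped by organ (needs ≥ 2 organs)
    vd = [(pr.organ, pr.vascular_density_px) for pr in profiles
          if np.isfinite(pr.vascular_density_px)]
    organs = sorted({o for o, _ in vd})
    if len(organs) >= 2:
        groups = [
            SampleGroup(o, np.array([v for oo, v in vd if oo == o])) for o in organs
        ]
        if all(g.n >= 1 for g in groups) and sum(g.n for g in groups) >= len(groups) + 1:
            kw = kruskal_wallis(groups)
            stats_rows.append({
                "section": cfg.section_id, "grouping": "vascular_density_by_organ",
                "channel": CHANNEL_CD31, "k": kw.k, "N": kw.n_total, "H": kw.H,
                "df": kw.df, "p": kw.p, "flags": ";".join(kw.flags),
            })
    else:
        man.warnings.append(
            "vascular-density KW by organ skipped (single organ in section)"
        )
    man.timings_s["stats"] = round(time.perf_counter() - t0, 4)

    p = tables / "stats.csv"
    with open(p, "w") as fh:
        fh.write(f"# {cfg.header()} n_max={a.n_max} alpha=0.05 "
                 f"note=single-section tests, no multiplicity correction\n")
        pd.DataFrame(
            stats_rows,
            columns=["section", "grouping", "channel", "k", "N", "H", "df", "p", "flags"],
        ).to_csv(fh, index=False)
    man.add_file(out, p)

    # vascular density vs marker expression across lesions
    corr_rows = []
    for ch in marker_channels:
        n_defined = sum(np.isfinite(pr.vascular_density_px) for pr in profiles)
        if n_defined >= 3:
            c = correlate_density_expression(profiles, ch)
            corr_rows.append({
                "section": cfg.section_id, "marker": ch, "rho": c.rho,
                "n": c.n, "p": c.p, "flags": ";".join(c.flags),
            })
        else:
            corr_rows.append({
                "section": cfg.section_id, "marker": ch, "rho": float("nan"),
                "n": n_defined, "p": float("nan"), "flags": "too_few_lesions",
            })
    p = tables / "correlation.csv"
    with open(p, "w") as fh:
        fh.write(f"# {cfg.header()} method=spearman\n")
        pd.DataFrame(corr_rows).to_csv(fh, index=False)
    man.add_file(out, p)

    man.write(out)
    return man


def _read_table(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise ConfigError(f"expected table missing: {path}; run analyze first")
    return pd.read_csv(path, comment="#")


def _require_columns(frame: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise ConfigError(f"{name}: missing required column(s) {missing}")


def bxp_stats_from_summary(bp: pd.DataFrame) -> list[dict]:
    """Translate a boxplot-summary table into matplotlib ``bxp`` stat dicts,
    so drawn quartiles/whiskers equal the table values exactly."""
    _require_columns(
        bp, ["group_id", "q1", "median", "q3", "whisker_lo", "whisker_hi"],
        "boxplot summary",
    )
    return [
        {
            "label": str(row["group_id"]),
            "whislo": row["whisker_lo"], "q1": row["q1"], "med": row["median"],
            "q3": row["q3"], "whishi": row["whisker_hi"], "fliers": [],
        }
        for _, row in bp.iterrows()
    ]


def run_report(cfg: PipelineConfig) -> RunManifest:
    """Render deterministic figures from the analyze-stage tables."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    man = RunManifest("report", cfg.seed, __version__, cfg.snapshot())
    out = cfg.out_dir
    tables = out / "tables"
    fig_dir = out / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)

    profiles = _read_table(tables / "profiles.csv")
    if profiles.empty:
        man.warnings.append("no lesions in profiles table; no figures drawn")
        man.write(out)
        return man
    _require_columns(profiles, ["roi_id", "vascular_density_um"], "profiles.csv")

    markers = cfg.report.markers
    if not markers:
        markers = sorted(
            c.removeprefix("mean_") for c in profiles.columns
            if c.startswith("mean_") and c not in ("mean_hoechst", "mean_cd31")
        )

    savefig = dict(dpi=cfg.report.dpi, metadata={"Software": "tumormap"})
    for marker in markers:
        hist_path = tables / f"histograms_{marker}.csv"
        if hist_path.exists():
            hist = _read_table(hist_path)
            fig, ax = plt.subplots(figsize=(6, 4))
            for col in [c for c in hist.columns if c != "intensity"]:
                ax.plot(hist["intensity"], hist[col], label=col.replace("roi_", "lesion "))
            ax.set_xlabel("intensity level (0–255)")
            ax.set_ylabel("% of ROI pixels")
            ax.set_title(f"{cfg.section_id}: {marker} intensity distributions")
            ax.legend(fontsize=7)
            p = fig_dir / f"{cfg.section_id}_hist_{marker}.png"
            fig.savefig(p, **savefig)
            plt.close(fig)
            man.add_file(out, p)

        bp_path = tables / f"boxplot_{marker}.csv"
        if bp_path.exists():
            bp = _read_table(bp_path)
            fig, ax = plt.subplots(figsize=(6, 4))
            ax.bxp(bxp_stats_from_summary(bp), showfliers=False)
            ax.set_xlabel("lesion")
            ax.set_ylabel(f"{marker} intensity")
            ax.set_title(f"{cfg.section_id}: {marker} per-lesion distribution")
            p = fig_dir / f"{cfg.section_id}_box_{marker}.png"
            fig.savefig(p, **savefig)
            plt.close(fig)
            man.add_file(out, p)

        col = f"mean_{marker}"
        if col in profiles.columns:
            defined = profiles[np.isfinite(profiles["vascular_density_um"])]
            n_excluded = len(profiles) - len(defined)
            fig, ax = plt.subplots(figsize=(5, 4))
            ax.scatter(defined["vascular_density_um"], defined[col])
            ax.set_xlabel("vascular density (mean nearest-CD31 distance, μm)")
            ax.set_ylabel(f"mean {marker} intensity")
            caption = f"{cfg.section_id}: n={len(defined)} lesions"
            if n_excluded:
                caption += f"; {n_excluded} excluded (undefined density)"
            ax.set_title(caption, fontsize=9)
            p = fig_dir / f"{cfg.section_id}_density_vs_{marker}.png"
            fig.savefig(p, **savefig)
            plt.close(fig)
            man.add_file(out, p)

    man.write(out)
    return man


def run_all(cfg: PipelineConfig) -> list[RunManifest]:
    manifests = []
    if cfg.synthetic is not None:
        manifests.append(run_simulate(cfg))
    manifests.append(run_analyze(cfg))
    manifests.append(run_report(cfg))
    return manifests
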