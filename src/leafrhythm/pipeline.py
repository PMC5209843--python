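"""High-level runs tying detection, analysis and comparison together.

These functions are what the CLI subcommands call; they read/write the CSV
contracts and log every parameter, so a run is reproducible from its inputs,
config and seed alone.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio

from . import io
from .config import Config
from .errors import LeafRhythmError
from .imaging import (PlateImageSeries, build_layout, detect_red_marks,
                      extract_traces, read_marks_file, segment_seedling,
                      write_overlay)
from .rhythm import analyze_series, choose_leaf, compare_groups
from .series import TimeSeries

log = logging.getLogger("leafrhythm")


def run_detect(images_dir, out_csv, config: Config | None = None,
               marks_file=None, overlay_dir=None) -> None:
    """Stage 1: image stack -> tip-position CSV (plus optional QC overlays)."""
    config = config or Config()
    stack = PlateImageSeries.from_directory(images_dir, config.interval_min)
    log.info("detect: %d frames from %s, interval %.3g min",
             len(stack.image_paths), images_dir, config.interval_min)
    first = iio.imread(stack.image_paths[0])
    if marks_file is not None:
        marks = read_marks_file(marks_file)
        log.info("detect: using marks override from %s", marks_file)
    else:
        marks = detect_red_marks(first, config)
    layout = build_layout(marks, config.rows, config.cols, config.layout_slack)
    log.info("detect: layout %dx%d, plate span %s", config.rows, config.cols,
             layout.plate_span)
    traces = extract_traces(stack, layout, config)
    for tr in traces:
        if not tr.usable:
            log.warning("detect: chamber %d unusable (detect rate %.2f < %.2f)",
                        tr.chamber_index, tr.detect_rate, config.detect_floor)
    io.write_positions_csv(io.ensure_parent(out_csv), traces, stack.times_h)
    if overlay_dir is not None:
        overlay_dir = Path(overlay_dir)
        overlay_dir.mkdir(parents=True, exist_ok=True)
        detections = [segment_seedling(first[y0:y1, x0:x1], ci, config)
                      for ci, (x0, x1, y0, y1) in enumerate(layout.chambers)]
        iio.imwrite(overlay_dir / "overlay.png",
                    write_overlay(first, layout, detections))
    log.info("detect: wrote %s", out_csv)


def analyze_traces(pairs: dict[str, dict[str, TimeSeries]],
                   config: Config) -> tuple[list[dict], dict[str, dict]]:
    """Fit every trace; apply the left-leaf preference per chamber.

    Returns the period-table rows and a mapping chamber -> chosen result
    (period_h, phase_h, leaf) for chambers where any leaf was rhythmic.
    """
    rows: list[dict] = []
    chosen: dict[str, dict] = {}
    for chamber, leaves in pairs.items():
        fits = {}
        for leaf in ("left", "right"):
            ts = leaves.get(leaf)
            if ts is None:
                continue
            try:
                fits[leaf] = analyze_series(ts, config)
            except LeafRhythmError as exc:
                log.warning("analyze: %s %s failed: %s", chamber, leaf, exc)
        if not fits:
            # chamber unusable (e.g. no plant ever detected): flag, keep the row
            for leaf, ts in leaves.items():
                rows.append({"trace_label": ts.label, "chamber": chamber,
                             "leaf": leaf, "period_h": None, "phase_h": None,
                             "amplitude_px": None, "rel_err": None,
                             "n_terms": 0, "status": "excluded"})
            continue
        both_arrhythmic = all(f.selected_period is None for f in fits.values())
        for leaf, fit in fits.items():
            status = "excluded" if both_arrhythmic else fit.status
            rows.append({
                "trace_label": leaves[leaf].label,
                "chamber": chamber,
                "leaf": leaf,
                "period_h": fit.selected_period,
                "phase_h": fit.selected_phase,
                "amplitude_px": fit.selected_amplitude,
                "rel_err": fit.rel_err[0] if fit.rel_err else None,
                "n_terms": fit.n_terms,
                "status": status,
            })
        pick = choose_leaf(fits.get("left") or _ARRHYTHMIC,
                           fits.get("right") or _ARRHYTHMIC)
        if pick is not None:
            leaf = "left" if pick is fits.get("left") else "right"
            chosen[chamber] = {"period_h": pick.selected_period,
                               "phase_h": pick.selected_phase, "leaf": leaf}
    return rows, chosen


class _Arrhythmic:
    selected_period = None
    selected_phase = None


_ARRHYTHMIC = _Arrhythmic()


def run_analyze(in_csv, out_csv, config: Config | None = None) -> list[dict]:
    """Stage 2: tip-position CSV -> per-trace periods CSV."""
    config = config or Config()
    pairs = io.trace_pairs(io.read_positions_csv(in_csv))
    log.info("analyze: %d chamber(s), window %s h, detrend=%s, alpha=%.3g",
             len(pairs), config.period_window, config.detrend, config.alpha)
    rows, chosen = analyze_traces(pairs, config)
    io.write_periods_csv(io.ensure_parent(out_csv), rows)
    log.info("analyze: %d/%d chambers rhythmic; wrote %s",
             len(chosen), len(pairs), out_csv)
    return rows


def run_compare(periods_csv, groups_csv, out_csv):
    """Group periods by label and run the two-sample Student's t test."""
    df = io.read_periods_csv(periods_csv)
    groups_map = io.read_groups_csv(groups_csv)
    periods: dict[str, list[float]] = {}
    for chamber, sub in df.groupby("chamber", sort=True):
        group = groups_map.get(str(chamber))
        if group is None:
            continue
        period = None
        for leaf in ("left", "right"):   # left-leaf preference
            row = sub[(sub["leaf"] == leaf) & (sub["status"] == "ok")]
            if len(row):
                period = float(row["period_h"].iloc[0])
                break
        if period is not None:
            periods.setdefault(group, []).append(period)
    result = compare_groups(periods)
    io.write_group_stats_csv(io.ensure_parent(out_csv), result)
    log.info("compare: %s n=%s mean=%s sd=%s; t=%.4g df=%d p=%.4g",
             result.labels, result.n,
             tuple(round(m, 3) for m in result.mean),
             tuple(round(s, 3) for s in result.sd),
             result.t_statistic, result.df, result.p_value)
    return result


def run_pipeline(images_or_csv, out_csv, config: Config | None = None,
                 groups_csv=None, stats_csv=None, **detect_kwargs) -> list[dict]:
    """Dispatch detect (if given a directory) then analyze, then compare.

    Deterministic given inputs + config + seed; any module error propagates
    so the CLI can map it to a nonzero exit code.
    """
    config = config or Config()
    src = Path(images_or_csv)
    if src.is_dir():
        positions = Path(out_csv).with_suffix(".positions.csv")
        run_detect(src, positions, config, **detect_kwargs)
        src = positions
    rows = run_analyze(src, out_csv, config)
    if groups_csv is not None:
        run_compare(out_csv, groups_csv,
                    stats_csv or Path(out_csv).with_suffix(".stats.csv"))
    return rows
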