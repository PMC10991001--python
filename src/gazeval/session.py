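"""Project-folder workflow: import -> annotate -> process -> export.

A project directory holds a poster configuration, a ``project.toml``
with processing options, imported recordings and per-recording results:

    project/
      project.toml      # mode, assumed distance, classifier parameters
      poster.toml       # poster geometry
      status.json       # per-recording workflow status
      recordings/<name>/    # interchange-format recordings
      results/<name>.csv    # per-episode, per-target measures

Recording status advances monotonically through imported ->
episodes_annotated -> dq_computed; processing a recording before its
validation episodes are annotated is refused with an actionable error.
"""

from __future__ import annotations

import hashlib
import json
import shutil
import tomllib
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import pandas as pd

from .fixations import ClassifierParams
from .poster import PosterSpec, default_poster, load_poster, save_poster
from .quality import process_recording, summarize
from .recording import EpisodeAnnotation, RecordingError, read_recording

__all__ = ["Status", "Project", "ProjectError"]


class ProjectError(RuntimeError):
    pass


class Status(IntEnum):
    NOT_IMPORTED = 0
    IMPORTED = 1
    EPISODES_ANNOTATED = 2
    DQ_COMPUTED = 3


_DEFAULT_CONFIG = """\
mode = "fixed_distance"        # or "pose_estimated"
assumed_distance_mm = 600.0
poster = "poster.toml"

[classifier]
window_ms = 200.0
max_interp_gap_ms = 100.0
weight_cutoff_lambda = 2.0
merge_max_gap_ms = 30.0
merge_max_dist_deg = 0.7
min_fix_dur_ms = 40.0
"""


@dataclass
class Project:
    root: Path

    @classmethod
    def init(cls, root: str | Path, poster: PosterSpec | None = None) -> "Project":
        """Create a project directory with the default configuration."""
        root = Path(root)
        root.mkdir(parents=True, exist_ok=True)
        (root / "recordings").mkdir(exist_ok=True)
        (root / "results").mkdir(exist_ok=True)
        cfg = root / "project.toml"
        if not cfg.exists():
            cfg.write_text(_DEFAULT_CONFIG)
        pf = root / "poster.toml"
        if not pf.exists():
            save_poster(poster or default_poster(), pf)
        st = root / "status.json"
        if not st.exists():
            st.write_text("{}")
        return cls(root=root)

    @classmethod
    def open(cls, root: str | Path) -> "Project":
        root = Path(root)
        if not (root / "project.toml").exists():
            raise ProjectError(f"{root} is not a project (missing project.toml)")
        return cls(root=root)

    # -- config ------------------------------------------------------------
    def config(self) -> dict:
        with open(self.root / "project.toml", "rb") as f:
            return tomllib.load(f)

    def poster(self) -> PosterSpec:
        return load_poster(self.root / self.config().get("poster", "poster.toml"))

    def classifier_params(self) -> ClassifierParams:
        c = self.config().get("classifier", {})
        return ClassifierParams(**c) if c else ClassifierParams()

    # -- status ------------------------------------------------------------
    def statuses(self) -> dict[str, Status]:
        d = json.loads((self.root / "status.json").read_text())
        return {k: Status(v) for k, v in d.items()}

    def _set_status(self, name: str, status: Status) -> None:
        d = json.loads((self.root / "status.json").read_text())
        d[name] = int(status)
        (self.root / "status.json").write_text(json.dumps(d, indent=1, sort_keys=True))

    # -- workflow ----------------------------------------------------------
    def import_recordings(self, dirs: list[str | Path]) -> dict[str, str]:
        """Copy interchange-format recordings into the project.

        Returns a per-recording report, "imported" or an error message;
        a malformed recording does not stop the others.  Re-importing an
        already imported recording is a no-op.
        """
        report: dict[str, str] = {}
        for src in dirs:
            src = Path(src)
            name = src.name
            dst = self.root / "recordings" / name
            if dst.exists() and self.statuses().get(name, Status.NOT_IMPORTED) >= Status.IMPORTED:
                report[name] = "imported"
                continue
            try:
                rec = read_recording(src)
            except (RecordingError, FileNotFoundError, ValueError) as exc:
                report[name] = f"error: {exc}"
                continue
            if dst.exists():
                shutil.rmtree(dst)
            shutil.copytree(src, dst)
            status = Status.IMPORTED
            if rec.episodes:
                # episodes shipped with the recording count as annotated
                status = Status.EPISODES_ANNOTATED
            self._set_status(name, status)
            report[name] = "imported"
        return report

    def annotate(self, name: str, episodes_csv: str | Path) -> None:
        """Attach validation-episode annotations to a recording."""
        if self.statuses().get(name, Status.NOT_IMPORTED) < Status.IMPORTED:
            raise ProjectError(f"recording '{name}' is not imported; run import first")
        df = pd.read_csv(episodes_csv)
        eps = [
            EpisodeAnnotation(float(r["start_ms"]), float(r["end_ms"]), str(r["label"]))
            for _, r in df.iterrows()
        ]
        eps.sort(key=lambda e: e.start)
        for a, b in zip(eps, eps[1:]):
            if b.start < a.end:
                raise RecordingError(f"episodes '{a.label}' and '{b.label}' overlap")
        df.to_csv(self.root / "recordings" / name / "episodes.csv", index=False)
        self._set_status(name, Status.EPISODES_ANNOTATED)

    def process(self, name: str) -> pd.DataFrame:
        """Map, classify, match and measure every annotated episode."""
        status = self.statuses().get(name, Status.NOT_IMPORTED)
        if status < Status.EPISODES_ANNOTATED:
            raise ProjectError(
                f"recording '{name}' has no annotated validation episodes; "
                "run annotate before process"
            )
        cfg = self.config()
        rec = read_recording(self.root / "recordings" / name)
        if not rec.episodes:
            raise ProjectError(f"recording '{name}' has an empty episodes.csv")
        summaries = process_recording(
            rec,
            self.poster(),
            mode=cfg.get("mode", "fixed_distance"),
            assumed_distance=cfg.get("assumed_distance_mm"),
            params=self.classifier_params(),
            recording_name=name,
        )
        df = summarize(summaries, average_over_targets=False)
        df.to_csv(self.root / "results" / f"{name}.csv", index=False)
        self._set_status(name, Status.DQ_COMPUTED)
        return df

    def export(
        self, average_over_targets: bool = False, xlsx: bool = False
    ) -> Path:
        """Write one summary file across all processed recordings.

        Also writes ``results/provenance.json`` recording the poster
        file hash, mode and classifier parameters used.
        """
        frames = []
        for name, status in sorted(self.statuses().items()):
            if status < Status.DQ_COMPUTED:
                continue
            frames.append(pd.read_csv(self.root / "results" / f"{name}.csv"))
        if not frames:
            raise ProjectError("no processed recordings to export")
        df = pd.concat(frames, ignore_index=True)
        if average_over_targets:
            group = ["recording", "episode", "episode_start_ms"]
            agg = (
                df.groupby(group, dropna=False)
                .agg(
                    mode=("mode", "first"),
                    data_loss_percent=("data_loss_percent", "first"),
                    gaze_range_h_deg=("gaze_range_h_deg", "first"),
                    gaze_range_v_deg=("gaze_range_v_deg", "first"),
                    accuracy_deg=("accuracy_deg", "mean"),
                    rms_s2s_deg=("rms_s2s_deg", "mean"),
                    std_deg=("std_deg", "mean"),
                    viewing_distance_mm=("viewing_distance_mm", "mean"),
                    n_samples=("n_samples", "sum"),
                    n_unmatched=("n_unmatched", "sum"),
                )
                .reset_index()
            )
            agg.insert(3, "target_id", "mean")
            df = agg
        out = self.root / "results" / ("summary.xlsx" if xlsx else "summary.csv")
        if xlsx:
            df.to_excel(out, index=False)
        else:
            df.to_csv(out, index=False)
        cfg = self.config()
        poster_path = self.root / cfg.get("poster", "poster.toml")
        prov = {
            "poster_sha256": hashlib.sha256(poster_path.read_bytes()).hexdigest(),
            "mode": cfg.get("mode", "fixed_distance"),
            "assumed_distance_mm": cfg.get("assumed_distance_mm"),
            "classifier": cfg.get("classifier", {}),
            "average_over_targets": average_over_targets,
        }
        (self.root / "results" / "provenance.json").write_text(
            json.dumps(prov, indent=1)
        )
        return out
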