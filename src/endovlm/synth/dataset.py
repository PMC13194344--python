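"""Dataset assembly: frames, records, JSONL manifest and PNG images."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .config import GeneratorConfig
from .procedures import Activity, LandmarkVector, sample_procedure
from .render import render_frame
from ..textproc import render_structured_description

_CHANNELS = ("image", "description", "report")
_START_DESCRIPTION = "step 0 : procedure start"
_HISTORY_CAP = 30   # pairs; lossless for a 250-token context window


@dataclass
class FrameRecord:
    procedure_id: int
    activity_index: int
    state_id: int
    frame_time: float
    image_path: str
    landmark_vector: LandmarkVector
    description_prev: str
    description_current: str
    description_next: str | None
    keyword: str
    report_history: list[tuple[str, str]]
    report_target: str
    t_procedure: float
    t_observation: float
    channel_mask: tuple[bool, bool, bool] = (True, True, True)

    def to_json(self) -> dict:
        d = {
            "procedure_id": self.procedure_id,
            "activity_index": self.activity_index,
            "state_id": self.state_id,
            "frame_time": round(self.frame_time, 4),
            "image_path": self.image_path,
            "labels": self.landmark_vector.to_string(),
            "description_prev": self.description_prev,
            "description_current": self.description_current,
            "description_next": self.description_next,
            "keyword": self.keyword,
            "report_history": [list(p) for p in self.report_history],
            "report_target": self.report_target,
            "t_procedure": round(self.t_procedure, 6),
            "t_observation": round(self.t_observation, 6),
            "channel_mask": list(self.channel_mask),
        }
        return d

    @classmethod
    def from_json(cls, d: dict) -> "FrameRecord":
        return cls(
            procedure_id=d["procedure_id"], activity_index=d["activity_index"],
            state_id=d["state_id"], frame_time=d["frame_time"],
            image_path=d["image_path"],
            landmark_vector=LandmarkVector.from_string(d["labels"]),
            description_prev=d["description_prev"],
            description_current=d["description_current"],
            description_next=d["description_next"], keyword=d["keyword"],
            report_history=[tuple(p) for p in d["report_history"]],
            report_target=d["report_target"], t_procedure=d["t_procedure"],
            t_observation=d["t_observation"],
            channel_mask=tuple(d["channel_mask"]))


@dataclass
class DatasetManifest:
    records: list[FrameRecord]
    generator_config: GeneratorConfig
    n_kept: int
    n_discarded: int
    root: Path | None = None

    @property
    def procedure_ids(self) -> list[int]:
        return sorted({r.procedure_id for r in self.records})

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "manifest.jsonl", "w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec.to_json()) + "\n")
        self.generator_config.save(out / "generator_config.yaml")
        with open(out / "counts.json", "w") as fh:
            json.dump({"kept": self.n_kept, "discarded": self.n_discarded}, fh)

    @classmethod
    def load(cls, out_dir) -> "DatasetManifest":
        out = Path(out_dir)
        records = []
        with open(out / "manifest.jsonl") as fh:
            for line in fh:
                records.append(FrameRecord.from_json(json.loads(line)))
        config = GeneratorConfig.load(out / "generator_config.yaml")
        with open(out / "counts.json") as fh:
            counts = json.load(fh)
        return cls(records=records, generator_config=config,
                   n_kept=counts["kept"], n_discarded=counts["discarded"],
                   root=out)


def build_dataset(config: GeneratorConfig, out_dir) -> DatasetManifest:
    """Generate a full synthetic dataset under `out_dir`.

    Frames are sampled at `frames_per_second` inside every activity; a
    fraction `missing_channel_rate` of candidate frames loses one randomly
    chosen channel and is discarded, mirroring the kept/discarded bookkeeping
    of an aligned multimodal corpus.  Every kept record carries all three
    channels.  Byte-identical output for identical (config, seed).
    """
    config.validate()
    out = Path(out_dir)
    img_dir = out / "images"
    try:
        img_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:                      # pragma: no cover
        raise OSError(f"cannot create dataset directory {img_dir}: {exc}")
    drop_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xD20]))
    records: list[FrameRecord] = []
    n_discarded = 0
    frame_uid = 0
    for pid in range(config.n_procedures):
        activities = sample_procedure(config, procedure_seed=pid)
        total = activities[-1].end_time
        descriptions = [render_structured_description(a).rendered_text
                        for a in activities]
        history: list[tuple[str, str]] = []
        for i, act in enumerate(activities):
            desc_prev = descriptions[i - 1] if i > 0 else _START_DESCRIPTION
            desc_next = descriptions[i + 1] if i + 1 < len(activities) else None
            n_frames = int(np.floor(act.duration * config.frames_per_second))
            times = act.start_time + np.arange(max(n_frames, 1)) / config.frames_per_second
            for t in times:
                frame_uid += 1
                if drop_rng.uniform() < config.missing_channel_rate:
                    n_discarded += 1     # one channel missing -> discard frame
                    drop_rng.integers(3)  # which channel (consumed for determinism)
                    continue
                img = render_frame(act.landmark_vector, config, frame_seed=frame_uid)
                rel = f"images/p{pid:02d}_f{frame_uid:06d}.png"
                Image.fromarray(img).save(out / rel)
                records.append(FrameRecord(
                    procedure_id=pid, activity_index=i, state_id=act.state_id,
                    frame_time=float(t), image_path=rel,
                    landmark_vector=act.landmark_vector,
                    description_prev=desc_prev,
                    description_current=descriptions[i],
                    description_next=desc_next, keyword=act.keyword,
                    report_history=list(history[-_HISTORY_CAP:]),
                    report_target=act.report_sentence,
                    t_procedure=float(t) / total,
                    t_observation=(float(t) - act.start_time) / act.duration))
            history.append((act.keyword, act.report_sentence))
    manifest = DatasetManifest(records=records, generator_config=config,
                               n_kept=len(records), n_discarded=n_discarded,
                               root=out)
    manifest.save(out)
    return manifest


def label_frequencies(manifest: DatasetManifest) -> np.ndarray:
    """Per-class frequency over kept frames (may sum above 1: multi-label)."""
    if not manifest.records:
        raise ValueError("empty manifest")
    bits = np.stack([r.landmark_vector.bits for r in manifest.records])
    return bits.mean(axis=0)


def load_image(manifest: DatasetManifest, record: FrameRecord) -> np.ndarray:
    """Load a record's frame as float32 in [0, 1], shape (H, W, 3)."""
    if manifest.root is None:
        raise ValueError("manifest has no root directory")
    path = Path(manifest.root) / record.image_path
    return np.asarray(Image.open(path), dtype=np.float32) / 255.0
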