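"""Mean-of-means threshold classification and the versioned model registry.

The triage rule places a cutoff at the midpoint of two class mean scores:
normal-vs-OPML gives the green/yellow boundary, OPML-vs-SCC the
yellow/red one.  Models are learned per site group (all sites,
keratinized, non-keratinized, or one anatomical site) because mucosal
optics differ by site, and the "normal" class can be sourced from patient
adjoining-normal tissue or from healthy volunteers — the latter avoids
field-cancerization bias and typically lowers the normal/OPML cutoff.

The feedback loop the device runs against a cloud service is emulated by
a local append-only registry: new confirmed scores are appended and the
model refit, yielding a new immutable version.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .bands import base_site, site_group
from .imageset import ScoreRecord

GROUPS_FIXED = ("all_sites", "keratinized", "non_keratinized")
CLASS_ORDER = ("normal", "suspect", "critical")
CLASS_COLOR = {"normal": "green", "suspect": "yellow", "critical": "red"}


def learn_threshold(scores_a: Sequence[float], scores_b: Sequence[float]) -> float:
    """Midpoint of the two class means (the mean-of-means rule).

    Depends only on the class means, not the class sizes.
    """
    if not scores_a or not scores_b:
        raise ValueError("both classes must be non-empty")
    if min(scores_a) <= 0 or min(scores_b) <= 0:
        raise ValueError("scores must be positive")
    return (statistics.fmean(scores_a) + statistics.fmean(scores_b)) / 2.0


@dataclass(frozen=True)
class ThresholdModel:
    """Two-cutoff triage model for one site group.

    ``t_opml`` separates normal (green) from suspect (yellow);
    ``t_scc`` separates suspect from critical (red).  Boundary scores go
    to the higher-risk class.
    """

    group: str
    t_opml: float
    t_scc: float
    provenance: dict = field(default_factory=dict)
    version: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.t_opml < self.t_scc:
            raise ValueError("cutoffs must satisfy 0 < t_opml < t_scc")

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "t_opml": self.t_opml,
            "t_scc": self.t_scc,
            "provenance": self.provenance,
            "version": self.version,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ThresholdModel":
        return cls(
            group=data["group"],
            t_opml=float(data["t_opml"]),
            t_scc=float(data["t_scc"]),
            provenance=data.get("provenance", {}),
            version=int(data.get("version", 1)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "ThresholdModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _in_group(record: ScoreRecord, group: str) -> bool:
    if group == "all_sites":
        return True
    if group in ("keratinized", "non_keratinized"):
        return site_group(record.anatomical_site) == group
    if group.startswith("site:"):
        term = group[len("site:") :]
        return record.anatomical_site == term or base_site(record.anatomical_site) == term
    raise ValueError(f"unknown group {group!r}")


def fit_model(
    records: Iterable[ScoreRecord],
    group: str = "all_sites",
    normal_source: str = "patient",
    version: int = 1,
) -> ThresholdModel:
    """Fit the two mean-of-means cutoffs on a labelled score table.

    Normal-class scores are restricted to ``normal_source`` (patient
    adjoining-normal vs healthy volunteer); OPML and SCC scores always
    come from patients.
    """
    by_class: dict[str, list[float]] = {"normal": [], "OPML": [], "SCC": []}
    for r in records:
        if not _in_group(r, group):
            continue
        if r.label == "normal" and r.source != normal_source:
            continue
        by_class[r.label].append(r.score)
    missing = [label for label, scores in by_class.items() if not scores]
    if missing:
        raise ValueError(f"group {group!r} lacks class(es) {missing} after filtering")

    t_opml = learn_threshold(by_class["normal"], by_class["OPML"])
    t_scc = learn_threshold(by_class["OPML"], by_class["SCC"])
    if t_opml >= t_scc:
        raise ValueError(
            f"degenerate training: t_opml={t_opml:.4g} >= t_scc={t_scc:.4g}"
        )
    provenance = {
        "n": {label: len(scores) for label, scores in by_class.items()},
        "class_means": {
            label: statistics.fmean(scores) for label, scores in by_class.items()
        },
        "normal_source": normal_source,
    }
    return ThresholdModel(
        group=group, t_opml=t_opml, t_scc=t_scc, provenance=provenance, version=version
    )


def classify(score: float, model: ThresholdModel) -> tuple[str, str]:
    """Assign a lesion score to a triage zone: ``(class, display_color)``.

    ``score < t_opml`` is normal/green; ``t_opml <= score < t_scc`` is
    suspect/yellow; ``score >= t_scc`` is critical/red.  Boundary values
    land in the higher-risk class (sensitivity-first).
    """
    if not score > 0:
        raise ValueError("score must be positive")
    if score < model.t_opml:
        cls = "normal"
    elif score < model.t_scc:
        cls = "suspect"
    else:
        cls = "critical"
    return cls, CLASS_COLOR[cls]


class ModelRegistry:
    """Local append-only training store with immutable model versions.

    Layout under ``root``: ``records.jsonl`` (one ScoreRecord per line,
    append-only) and ``models/<group>/v<N>.json`` snapshots.  Refitting a
    group after appending records increments that group's version; every
    historical version stays retrievable and can be reproduced by
    replaying the log.
    """

    def __init__(self, root: str | Path):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)
        self._records_path = self.root / "records.jsonl"
        (self.root / "models").mkdir(exist_ok=True)

    # -- training log -------------------------------------------------

    def append_records(self, records: Iterable[ScoreRecord]) -> int:
        n = 0
        with self._records_path.open("a") as fh:
            for r in records:
                fh.write(
                    json.dumps(
                        {
                            "site_id": r.site_id,
                            "anatomical_site": r.anatomical_site,
                            "score": r.score,
                            "label": r.label,
                            "source": r.source,
                        }
                    )
                    + "\n"
                )
                n += 1
        return n

    def records(self, upto: int | None = None) -> list[ScoreRecord]:
        """All stored records, optionally truncated to the first ``upto``."""
        if not self._records_path.exists():
            return []
        out = []
        with self._records_path.open() as fh:
            for i, line in enumerate(fh):
                if upto is not None and i >= upto:
                    break
                d = json.loads(line)
                out.append(ScoreRecord(**d))
        return out

    # -- model versions ------------------------------------------------

    def _group_dir(self, group: str) -> Path:
        safe = group.replace(":", "_")
        return self.root / "models" / safe

    def versions(self, group: str) -> list[int]:
        d = self._group_dir(group)
        if not d.exists():
            return []
        return sorted(int(p.stem[1:]) for p in d.glob("v*.json"))

    def latest(self, group: str) -> ThresholdModel:
        versions = self.versions(group)
        if not versions:
            raise KeyError(f"no model fitted yet for group {group!r}")
        return self.get(group, versions[-1])

    def get(self, group: str, version: int) -> ThresholdModel:
        path = self._group_dir(group) / f"v{version}.json"
        if not path.exists():
            raise KeyError(f"no model version {version} for group {group!r}")
        return ThresholdModel.load(path)

    def _store(self, model: ThresholdModel, n_records: int) -> ThresholdModel:
        d = self._group_dir(model.group)
        d.mkdir(parents=True, exist_ok=True)
        snapshot = ThresholdModel(
            group=model.group,
            t_opml=model.t_opml,
            t_scc=model.t_scc,
            provenance={**model.provenance, "n_records_seen": n_records},
            version=model.version,
        )
        path = d / f"v{snapshot.version}.json"
        if path.exists():
            raise RuntimeError(f"refusing to overwrite immutable snapshot {path}")
        snapshot.save(path)
        return snapshot


def update_model(
    registry: ModelRegistry,
    new_records: Iterable[ScoreRecord],
    group: str = "all_sites",
    normal_source: str = "patient",
) -> ThresholdModel:
    """Append confirmed scores and refit the group's model (next version)."""
    registry.append_records(new_records)
    all_records = registry.records()
    version = (registry.versions(group)[-1] + 1) if registry.versions(group) else 1
    model = fit_model(all_records, group=group, normal_source=normal_source, version=version)
    return registry._store(model, n_records=len(all_records))


def replay_versions(registry: ModelRegistry, group: str) -> list[ThresholdModel]:
    """Rebuild every stored version of a group's model from the log alone.

    Uses each snapshot's recorded log length; the rebuilt cutoffs must
    match the stored ones exactly, which the test suite asserts.
    """
    rebuilt = []
    for v in registry.versions(group):
        stored = registry.get(group, v)
        n_seen = stored.provenance.get("n_records_seen")
        records = registry.records(upto=n_seen)
        rebuilt.append(
            fit_model(
                records,
                group=group,
                normal_source=stored.provenance.get("normal_source", "patient"),
                version=v,
            )
        )
    return rebuilt
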