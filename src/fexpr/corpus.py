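"""Corpus data model and curation.

A :class:`Corpus` bundles apex-frame records (landmarks + raster + metadata),
a long-format judge-rating table and a subject covariate table. Curation
operations implement the study protocol around such data: retaining only
well-produced expressions (mean target-scale rating strictly above a
threshold), inter-rater reliability (ICC), construction of a covariate- and
label-matched subgroup from the larger group, and export of the per-video
modelling table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd
from PIL import Image

from .landmarks import EMOTIONS, N_LANDMARKS

#: metadata columns, in file order
METADATA_COLUMNS = ["video_id", "subject_id", "group", "age", "gender", "site",
                    "order", "task", "modality", "target_emotion"]


class MatchingError(RuntimeError):
    """Raised when subgroup matching is infeasible for some subject."""


@dataclass
class FrameRecord:
    """One video's apex frame: landmarks, raster and metadata."""

    video_id: str
    subject_id: str
    group: str
    target_emotion: str
    task: str               # "imitation" | "on_request"
    modality: str           # "visual" | "audio-visual"
    landmarks: np.ndarray   # (49, 2) pixel coordinates
    image: np.ndarray | None = None   # (H, W) uint8 grayscale
    mixture: Any = None     # realized emotion mixture, when synthetic

    def __post_init__(self) -> None:
        self.landmarks = np.asarray(self.landmarks, dtype=float)
        if self.landmarks.shape != (N_LANDMARKS, 2):
            raise ValueError(
                f"{self.video_id}: expected ({N_LANDMARKS}, 2) landmarks, "
                f"got {self.landmarks.shape}")
        if self.target_emotion not in EMOTIONS:
            raise ValueError(f"unknown emotion {self.target_emotion!r}")


@dataclass
class Corpus:
    """Frames, ratings and subject covariates for one collection of videos.

    ``ratings`` is long-format with columns
    ``video_id, judge_id, emotion, score`` (integer scores 0-10, all four
    emotion scales per judge per video). ``subjects`` has one row per
    subject with columns ``subject_id, group, age, gender, site, order``.
    """

    frames: list[FrameRecord]
    ratings: pd.DataFrame
    subjects: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def video_ids(self) -> list[str]:
        return [f.video_id for f in self.frames]

    def get(self, video_id: str) -> FrameRecord:
        for f in self.frames:
            if f.video_id == video_id:
                return f
        raise KeyError(video_id)

    def metadata(self) -> pd.DataFrame:
        """One row per video: identifiers, covariates, task and label."""
        rows = []
        covars = self.subjects.set_index("subject_id")
        for f in self.frames:
            c = covars.loc[f.subject_id]
            rows.append({
                "video_id": f.video_id, "subject_id": f.subject_id,
                "group": f.group, "age": c["age"], "gender": c["gender"],
                "site": c["site"], "order": c["order"], "task": f.task,
                "modality": f.modality, "target_emotion": f.target_emotion,
            })
        return pd.DataFrame(rows, columns=METADATA_COLUMNS)

    def subset(self, video_ids: Iterable[str]) -> "Corpus":
        """Corpus restricted to the given videos (corpus order preserved);
        subjects without a surviving video are dropped."""
        keep = set(video_ids)
        frames = [f for f in self.frames if f.video_id in keep]
        ratings = self.ratings[self.ratings["video_id"].isin(keep)].reset_index(drop=True)
        live_subjects = {f.subject_id for f in frames}
        subjects = self.subjects[
            self.subjects["subject_id"].isin(live_subjects)].reset_index(drop=True)
        return Corpus(frames=frames, ratings=ratings, subjects=subjects,
                      manifest=dict(self.manifest))

    def group(self, name: str) -> "Corpus":
        return self.subset([f.video_id for f in self.frames if f.group == name])

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for f in self.frames:
            seen.setdefault(f.group, None)
        return list(seen)

    def validate(self) -> None:
        """Check corpus invariants; raise ValueError on violation."""
        vids = set(self.video_ids)
        if len(vids) != len(self.frames):
            raise ValueError("duplicate video ids")
        if not set(self.ratings["video_id"]).issubset(vids):
            raise ValueError("ratings reference unknown video ids")
        scores = self.ratings["score"]
        if len(scores) and not ((scores >= 0) & (scores <= 10)).all():
            raise ValueError("scores outside [0, 10]")
        subj = set(self.subjects["subject_id"])
        frame_subj = {f.subject_id for f in self.frames}
        if not frame_subj.issubset(subj):
            raise ValueError("frames reference unknown subjects")
        if subj - frame_subj:
            raise ValueError("subjects with zero videos")


def mean_target_scores(corpus: Corpus) -> pd.Series:
    """Across-judge mean score on each video's target-emotion scale."""
    if corpus.ratings.empty:
        raise ValueError("corpus has no ratings")
    target = pd.Series({f.video_id: f.target_emotion for f in corpus.frames},
                       name="target_emotion")
    r = corpus.ratings.merge(target.rename("target"), left_on="video_id",
                             right_index=True)
    r = r[r["emotion"] == r["target"]]
    return r.groupby("video_id")["score"].mean().reindex(corpus.video_ids)


def quality_filter(corpus: Corpus, threshold: float = 7.0) -> Corpus:
    """Retain videos whose mean target-scale rating is strictly above
    ``threshold`` (a mean of exactly the threshold is excluded).

    Subjects left without any video are dropped from the subject table.
    """
    if not 0 <= threshold <= 10:
        raise ValueError("threshold must be in [0, 10]")
    means = mean_target_scores(corpus)
    keep = means[means > threshold].index
    return corpus.subset(keep)


def icc(ratings: pd.DataFrame, emotion_scale: str, form: str = "ICC2") -> float:
    """Inter-rater agreement on one emotion scale.

    Two-way random-effects, absolute-agreement, single-rater ICC (ICC(2,1))
    by default. Requires >= 2 judges and >= 2 videos with complete scores.
    A degenerate table with zero total variance is defined as 0 (with a
    warning).
    """
    sub = ratings[ratings["emotion"] == emotion_scale]
    table = sub.pivot(index="video_id", columns="judge_id", values="score")
    if table.isna().any().any():
        raise ValueError(f"incomplete rating table for scale {emotion_scale!r}")
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("ICC needs at least 2 videos and 2 judges")
    if np.allclose(table.to_numpy().var(), 0):
        warnings.warn("zero total variance; ICC defined as 0", RuntimeWarning,
                      stacklevel=2)
        return 0.0
    import pingouin as pg

    long = table.reset_index().melt(id_vars="video_id", var_name="judge_id",
                                    value_name="score")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pg.intraclass_corr(data=long, targets="video_id",
                                 raters="judge_id", ratings="score")
    # accept both Shrout-Fleiss and McGraw-Wong type labels
    aliases = {"ICC1": "ICC(1,1)", "ICC2": "ICC(A,1)", "ICC3": "ICC(C,1)",
               "ICC1k": "ICC(1,k)", "ICC2k": "ICC(A,k)", "ICC3k": "ICC(C,k)"}
    types = res.set_index("Type")["ICC"]
    key = form if form in types.index else aliases.get(form, form)
    value = float(types.loc[key])
    if not np.isfinite(value):
        warnings.warn("degenerate ICC table; ICC defined as 0", RuntimeWarning,
                      stacklevel=2)
        return 0.0
    return value


def group_icc(corpus: Corpus, group: str | None = None) -> pd.Series:
    """ICC per emotion scale for one group (or the whole corpus)."""
    sub = corpus.group(group) if group is not None else corpus
    return pd.Series({e: icc(sub.ratings, e) for e in EMOTIONS}, name="icc")


def matched_subgroup(corpus: Corpus, reference_group: str, seed: int = 0,
                     source_group: str | None = None,
                     age_caliper: float = 1.0) -> Corpus:
    """Build a subgroup of the (larger) source group matched to the
    reference group on gender, site and age, with the reference group's
    per-emotion video counts.

    Greedy seeded matching: reference subjects are processed in table
    order; each takes an unused source subject of identical gender and
    site with age within ``age_caliper`` years, minimising the absolute
    age difference (ties prefer a self-match, then video-rich subjects,
    so self-matching returns the reference itself and the video pool
    stays large). The matched subjects' videos are then subsampled per
    emotion to the reference counts.
    """
    subjects = corpus.subjects
    ref = subjects[subjects["group"] == reference_group]
    if ref.empty:
        raise ValueError(f"no subjects in reference group {reference_group!r}")
    if source_group is None:
        others = [g for g in corpus.groups if g != reference_group]
        if len(others) != 1:
            raise ValueError("source_group must be named explicitly")
        source_group = others[0]
    src = subjects[subjects["group"] == source_group]
    if source_group != reference_group and len(src) <= len(ref):
        raise ValueError("source group must be strictly larger than reference")

    rng = np.random.default_rng(seed)
    available = src.set_index("subject_id")
    # per-subject emotion profiles, used to keep the matched video pool
    # at least as rich as the reference profile (the study also matched
    # on the number of videos per targeted emotion)
    profile: dict[str, dict[str, int]] = {}
    for f in corpus.frames:
        profile.setdefault(f.subject_id, {e: 0 for e in EMOTIONS})
        profile[f.subject_id][f.target_emotion] += 1

    ref_vids = [f for f in corpus.frames if f.group == reference_group]
    ref_counts = pd.Series([f.target_emotion for f in ref_vids]).value_counts()
    pool_counts = {e: 0 for e in EMOTIONS}

    def coverage(candidate: str) -> int:
        """Videos this candidate adds toward the remaining per-emotion need."""
        c = profile.get(candidate, {})
        return sum(min(c.get(e, 0),
                       max(0, int(ref_counts.get(e, 0)) - pool_counts[e]))
                   for e in EMOTIONS)

    used: set[str] = set()
    matched: list[str] = []
    for _, r in ref.iterrows():
        cand = available[(available["gender"] == r["gender"])
                         & (available["site"] == r["site"])
                         & ((available["age"] - r["age"]).abs() <= age_caliper)]
        cand = cand.loc[[c for c in cand.index if c not in used]]
        if cand.empty:
            raise MatchingError(
                f"no match for subject {r['subject_id']} "
                f"(gender={r['gender']}, site={r['site']}, age={r['age']})")
        rid = r["subject_id"]
        ranked = sorted(
            cand.index,
            key=lambda c: (abs(cand.loc[c, "age"] - r["age"]),
                           c != rid, -coverage(c), str(c)))
        pick = ranked[0]
        used.add(pick)
        matched.append(pick)
        for e in EMOTIONS:
            pool_counts[e] += profile.get(pick, {}).get(e, 0)

    # per-emotion video subsampling to the reference label profile
    pool = [f for f in corpus.frames if f.subject_id in set(matched)]
    keep_ids: list[str] = []
    for emotion in EMOTIONS:
        need = int(ref_counts.get(emotion, 0))
        have = [f.video_id for f in pool if f.target_emotion == emotion]
        if len(have) < need:
            raise MatchingError(
                f"matched subjects have {len(have)} {emotion!r} videos, "
                f"need {need}")
        if len(have) == need:
            keep_ids.extend(have)
        else:
            keep_ids.extend(rng.choice(have, size=need, replace=False))
    return corpus.subset(keep_ids)


def label_distribution(corpus: Corpus) -> pd.DataFrame:
    """Per-group, per-emotion video counts and within-group percentages."""
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    meta = corpus.metadata()
    rows = []
    for g in corpus.groups:
        sub = meta[meta["group"] == g]
        total = len(sub)
        for e in EMOTIONS:
            n = int((sub["target_emotion"] == e).sum())
            pct = 100.0 * n / total if total else 0.0
            rows.append({"group": g, "emotion": e, "count": n, "percent": pct})
    return pd.DataFrame(rows)


def export_model_table(corpus: Corpus, path: str | Path | None = None) -> pd.DataFrame:
    """One row per video for downstream mixed-effects modelling.

    Columns: score (mean judge rating on the target scale), age, gender,
    order, task, modality, emotion, site, group, subject_id. Written as
    CSV when ``path`` is given.
    """
    means = mean_target_scores(corpus)
    meta = corpus.metadata().set_index("video_id")
    table = pd.DataFrame({
        "score": means,
        "age": meta["age"], "gender": meta["gender"], "order": meta["order"],
        "task": meta["task"], "modality": meta["modality"],
        "emotion": meta["target_emotion"], "site": meta["site"],
        "group": meta["group"], "subject_id": meta["subject_id"],
    })
    if path is not None:
        table.to_csv(path, index_label="video_id")
    return table


# ---------------------------------------------------------------------------
# corpus directory I/O
# ---------------------------------------------------------------------------

def write_corpus(corpus: Corpus, out_dir: str | Path) -> Path:
    """Write the corpus directory layout.

    ``landmarks/<video_id>.csv`` (index,x,y), ``frames/<video_id>.png``,
    ``ratings.csv``, ``metadata.csv`` and ``manifest.json``.
    """
    out = Path(out_dir)
    (out / "landmarks").mkdir(parents=True, exist_ok=True)
    has_images = any(f.image is not None for f in corpus.frames)
    if has_images:
        (out / "frames").mkdir(exist_ok=True)
    for f in corpus.frames:
        lm = pd.DataFrame(f.landmarks, columns=["x", "y"])
        lm.to_csv(out / "landmarks" / f"{f.video_id}.csv", index_label="index")
        if f.image is not None:
            Image.fromarray(f.image).save(out / "frames" / f"{f.video_id}.png")
    corpus.ratings.to_csv(out / "ratings.csv", index=False)
    corpus.metadata().to_csv(out / "metadata.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(corpus.manifest, fh, indent=2, default=str)
    return out


def read_corpus(in_dir: str | Path) -> Corpus:
    """Read a corpus directory written by :func:`write_corpus`."""
    src = Path(in_dir)
    meta = pd.read_csv(src / "metadata.csv")
    ratings = pd.read_csv(src / "ratings.csv")
    manifest = {}
    manifest_path = src / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
    frames = []
    for _, row in meta.iterrows():
        vid = row["video_id"]
        lm = pd.read_csv(src / "landmarks" / f"{vid}.csv")[["x", "y"]].to_numpy()
        img_path = src / "frames" / f"{vid}.png"
        image = np.asarray(Image.open(img_path)) if img_path.exists() else None
        frames.append(FrameRecord(
            video_id=vid, subject_id=row["subject_id"], group=row["group"],
            target_emotion=row["target_emotion"], task=row["task"],
            modality=row["modality"], landmarks=lm, image=image))
    subjects = (meta[["subject_id", "group", "age", "gender", "site", "order"]]
                .drop_duplicates("subject_id").reset_index(drop=True))
    return Corpus(frames=frames, ratings=ratings, subjects=subjects,
                  manifest=manifest)
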