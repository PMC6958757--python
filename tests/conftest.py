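import numpy as np
import pandas as pd
import pytest

from fexpr import (AMBIGUOUS_GROUP, CLEAR_GROUP, Corpus, CorpusConfig,
                   Demographics, FrameRecord, GroupSpec, generate_corpus,
                   make_template)
from fexpr.landmarks import EMOTIONS

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=25,
                              deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def template():
    return make_template()


@pytest.fixture(scope="session")
def small_corpus():
    """A small rendered two-group corpus shared by unit tests."""
    cfg = CorpusConfig(
        groups=(GroupSpec("clear", CLEAR_GROUP, 12,
                          Demographics(age_range=(6, 11), p_male=0.52,
                                       p_site_a=0.60)),
                GroupSpec("ambiguous", AMBIGUOUS_GROUP, 10,
                          Demographics(age_range=(6, 12), p_male=0.75,
                                       p_site_a=0.556))),
        videos_per_subject=(3, 5),
        seed=123,
    )
    return generate_corpus(cfg)


def toy_corpus(target_scores: dict[str, list[int]],
               emotion: str = "happiness",
               subject_of: dict[str, str] | None = None) -> Corpus:
    """Build a minimal corpus with prescribed target-scale judge scores.

    Non-target scales are rated 0 by every judge. One subject per video
    unless ``subject_of`` maps video ids to subject ids.
    """
    pts = make_template().points
    frames, rows, subj = [], [], {}
    for vid, scores in target_scores.items():
        sid = (subject_of or {}).get(vid, f"s-{vid}")
        frames.append(FrameRecord(
            video_id=vid, subject_id=sid, group="clear",
            target_emotion=emotion, task="imitation", modality="visual",
            landmarks=pts))
        subj[sid] = {"subject_id": sid, "group": "clear", "age": 8,
                     "gender": "F", "site": "Nice", "order": 1}
        for j, s in enumerate(scores):
            for e in EMOTIONS:
                rows.append({"video_id": vid, "judge_id": f"judge{j}",
                             "emotion": e, "score": s if e == emotion else 0})
    return Corpus(frames=frames, ratings=pd.DataFrame(rows),
                  subjects=pd.DataFrame(list(subj.values())))
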