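import numpy as np
import pytest

from fastpool.infer import PredictionRecord
from fastpool.synthetic import SyntheticConfig, simulate_dataset


def make_record(video_id: str, score: float, true_label: str,
                threshold: float = 0.5) -> PredictionRecord:
    """A prediction record with a single synthetic window score."""
    return PredictionRecord(
        video_id=video_id, window_scores=[(1.0 - score, score)],
        video_score=score, threshold=threshold,
        predicted_label="positive" if score >= threshold else "negative",
        true_label=true_label)


def random_records(rng: np.random.Generator, n: int,
                   informative: bool = True) -> list[PredictionRecord]:
    labels = rng.integers(0, 2, n)
    if informative:
        scores = np.clip(rng.normal(0.35 + 0.3 * labels, 0.2), 0.0, 1.0)
    else:
        scores = rng.uniform(0.0, 1.0, n)
    return [make_record(f"v{i}", float(scores[i]),
                        "positive" if labels[i] else "negative")
            for i in range(n)]


@pytest.fixture(scope="session")
def micro_config() -> SyntheticConfig:
    """Smallest legal dataset config: 2 subjects, 1 s sweeps at 10 FPS."""
    return SyntheticConfig(image_height=32, image_width=32, fps=10.0,
                           duration_s=1.0, n_subjects=2, videos_per_subject=2,
                           seed=11)


@pytest.fixture(scope="session")
def micro_dataset(micro_config):
    return simulate_dataset(micro_config)
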