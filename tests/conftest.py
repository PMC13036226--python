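"""Shared fixtures and independent naive oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from mmfluorfuse.classifier import MmVitnNetClassifier
from mmfluorfuse.data import FluorImage, ParameterRecord, center_crop, resize
from mmfluorfuse.features import apply_reduction, fit_reduction
from mmfluorfuse.model import ModelConfig
from mmfluorfuse.synthetic import PARAM_NAMES, GeneratorConfig, generate_dataset
from mmfluorfuse.training import TrainConfig

settings.register_profile("ci", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("ci")


def make_record(qy: float = 0.5, seed: int = 0, sample_id: str = "S0") -> ParameterRecord:
    """A syntactically valid 80-parameter record with a chosen QY_max."""
    rng = np.random.default_rng(seed)
    values = {name: float(v) for name, v in
              zip(PARAM_NAMES, rng.normal(size=len(PARAM_NAMES)))}
    values["QY_max"] = float(qy)
    return ParameterRecord(sample_id=sample_id, variety_id="V0",
                           treatment="salt", values=values)


def tiny_model_config(**overrides) -> ModelConfig:
    """A reduced-width configuration that runs in milliseconds on CPU."""
    base = dict(stage_depths=(1, 1, 1, 1), stage_widths=(8, 16, 24, 32),
                heads=(2, 2, 2, 4), window=2, img_size=64)
    base.update(overrides)
    return ModelConfig(**base)


# --------------------------------------------------- naive attention oracle

def naive_multihead_attention(x_q: np.ndarray, x_kv: np.ndarray, p) -> np.ndarray:
    """O(N^2) two-loop reference for scaled dot-product multi-head attention.

    ``p`` carries (wq, wk, wv, wo, b*) arrays and the head count; written
    deliberately element-by-element, independent of the library path.
    """
    wq, wk, wv, wo = p.wq.data, p.wk.data, p.wv.data, p.wo.data
    bq, bk, bv, bo = p.bq.data, p.bk.data, p.bv.data, p.bo.data
    h = p.heads
    c = wq.shape[0]
    d = c // h
    q = x_q @ wq + bq
    k = x_kv @ wk + bk
    v = x_kv @ wv + bv
    nq, nk = q.shape[0], k.shape[0]
    merged = np.zeros((nq, c))
    for head in range(h):
        sl = slice(head * d, (head + 1) * d)
        for i in range(nq):
            scores = np.empty(nk)
            for j in range(nk):
                scores[j] = q[i, sl] @ k[j, sl] / np.sqrt(d)
            w = np.exp(scores - scores.max())
            w /= w.sum()
            merged[i, sl] = sum(w[j] * v[j, sl] for j in range(nk))
    return merged @ wo + bo


def naive_calinski_harabasz(points: np.ndarray, labels: np.ndarray) -> float:
    """Brute-force two-loop B and W computation."""
    mu = points.mean(axis=0)
    n = len(points)
    uniq = sorted(set(labels.tolist()))
    k = len(uniq)
    B = W = 0.0
    for u in uniq:
        cl = points[labels == u]
        cmu = cl.mean(axis=0)
        for x in cl:
            W += float(((x - cmu) ** 2).sum())
        B += len(cl) * float(((cmu - mu) ** 2).sum())
    return (B / (k - 1)) / (W / (n - k))


# -------------------------------------------------------- heavy shared runs

@pytest.fixture(scope="session")
def overfit_run():
    """Train the reduced-width classifier on 60 synthetic samples, 30 epochs.

    Shared by the training-loop tests and the end-to-end learning check so
    the run happens once per session.
    """
    gcfg = GeneratorConfig(n_samples=60, seed=1, image_size=(96, 96))
    samples, _ = generate_dataset(gcfg)
    imgs = np.stack([resize(center_crop(s.image, 96), 64).pixels for s in samples])
    recs = [s.params for s in samples]
    levels = np.array([s.level for s in samples])
    red = fit_reduction(recs, k=6)
    text = np.stack([apply_reduction(red, r).values for r in recs])

    clf = MmVitnNetClassifier(
        model_config=tiny_model_config(),
        train_config=TrainConfig(batch_size=16, epochs=30, lr_max=3e-3,
                                 lr_min=1e-5, seed=0),
        seed=0)
    clf.fit((imgs, text), levels)
    return {"clf": clf, "images": imgs, "text": text, "levels": levels}
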