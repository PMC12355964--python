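"""Trainable disambiguation of the confusable micro/milli glyphs.

A misread between "μ" (micro) and "m" (milli) shifts a concentration by
a factor of exactly 1000, so a units-aware OCR stage needs a classifier
over {m, mu, other}.  This module renders a synthetic labeled glyph set
(multiple fonts, sizes, small rotations, Gaussian noise, downsampling)
and trains a compact multilayer-perceptron image classifier on 32x32
grayscale crops.  The model class is injectable; anything exposing
``fit``/``predict_proba`` over flattened pixel vectors can be swapped in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
from PIL import Image, ImageDraw, ImageFont

LABELS = ("m", "mu", "other")
IMAGE_SIZE = 32

_CLASS_GLYPHS = {"m": ("m",), "mu": ("μ", "µ"), "other": ("u", "n", "w", "h", "rn")}


class FontUnavailableError(EnvironmentError):
    pass


def default_fonts() -> list[str]:
    """TrueType fonts bundled with matplotlib (DejaVu family), which
    cover both the Greek mu and the micro sign."""
    import matplotlib

    ttf = Path(matplotlib.get_data_path()) / "fonts" / "ttf"
    names = ("DejaVuSans.ttf", "DejaVuSerif.ttf", "DejaVuSansMono.ttf")
    fonts = [str(ttf / n) for n in names if (ttf / n).exists()]
    if not fonts:
        raise FontUnavailableError(
            "no usable TrueType font found; pass explicit font paths to "
            "render_glyphs(fonts=[...])")
    return fonts


@dataclass
class GlyphSample:
    pixels: np.ndarray  # (32, 32) float in [0, 1]; 1 = ink
    label: str
    meta: dict = field(default_factory=dict)


@dataclass
class GlyphTrainConfig:
    epochs: int = 10
    learning_rate: float = 0.001
    optimizer: str = "adam"
    seed: int = 0
    hidden_layer_sizes: tuple[int, ...] = (128,)
    batch_size: int = 32

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


def _render_one(char: str, font_path: str, point_size: int, rotation: float,
                noise: float, rng: np.random.Generator) -> np.ndarray:
    scale = 2  # render large, then downsample (anti-aliasing)
    canvas = IMAGE_SIZE * scale
    img = Image.new("L", (canvas, canvas), 255)
    draw = ImageDraw.Draw(img)
    font = ImageFont.truetype(font_path, point_size * scale)
    left, top, right, bottom = draw.textbbox((0, 0), char, font=font)
    x = (canvas - (right - left)) // 2 - left
    y = (canvas - (bottom - top)) // 2 - top
    draw.text((x, y), char, fill=0, font=font)
    if rotation:
        img = img.rotate(rotation, resample=Image.BILINEAR, fillcolor=255)
    img = img.resize((IMAGE_SIZE, IMAGE_SIZE), Image.LANCZOS)
    arr = 1.0 - np.asarray(img, dtype=np.float64) / 255.0
    if noise > 0:
        arr = arr + rng.normal(0.0, noise, arr.shape)
    return np.clip(arr, 0.0, 1.0)


def render_glyphs(n_per_class: int, fonts: Sequence[str] | None = None,
                  noise_levels: Sequence[float] = (0.0, 0.03, 0.06),
                  seed: int = 0) -> list[GlyphSample]:
    """Render a balanced labeled glyph set; deterministic for a fixed
    seed.  Augmentations: font, point size 16-24, rotation up to ±5°,
    Gaussian pixel noise, 2x downsampling."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    fonts = list(fonts) if fonts else default_fonts()
    rng = np.random.default_rng(seed)
    samples: list[GlyphSample] = []
    for label in LABELS:
        glyphs = _CLASS_GLYPHS[label]
        for i in range(n_per_class):
            char = glyphs[int(rng.integers(len(glyphs)))]
            font = fonts[int(rng.integers(len(fonts)))]
            size = int(rng.integers(16, 25))
            rot = float(rng.uniform(-5.0, 5.0))
            noise = float(noise_levels[int(rng.integers(len(noise_levels)))])
            pixels = _render_one(char, font, size, rot, noise, rng)
            samples.append(GlyphSample(
                pixels=pixels, label=label,
                meta={"char": char, "font": Path(font).name, "point_size": size,
                      "rotation": rot, "noise": noise, "seed": seed, "index": i}))
    return samples


class GlyphModel:
    """Trained classifier over {m, mu, other}; probabilities sum to 1."""

    def __init__(self, estimator, config: GlyphTrainConfig) -> None:
        self.estimator = estimator
        self.config = config

    def classify(self, pixels: np.ndarray) -> tuple[str, dict[str, float]]:
        x = np.asarray(pixels, dtype=np.float64).reshape(1, -1)
        proba = self.estimator.predict_proba(x)[0]
        classes = list(self.estimator.classes_)
        probs = {c: float(p) for c, p in zip(classes, proba)}
        return classes[int(np.argmax(proba))], probs

    def save(self, path: str | Path) -> None:
        joblib.dump({"estimator": self.estimator, "config": self.config}, path)

    @classmethod
    def load(cls, path: str | Path) -> "GlyphModel":
        d = joblib.load(path)
        return cls(d["estimator"], d["config"])


def train(samples: Sequence[GlyphSample], cfg: GlyphTrainConfig | None = None,
          estimator=None) -> GlyphModel:
    """Train the classifier for ``cfg.epochs`` passes with the configured
    optimizer and learning rate.  Single-class input is an error."""
    cfg = cfg or GlyphTrainConfig()
    labels = sorted({s.label for s in samples})
    if len(labels) < 2:
        raise ValueError("training requires at least two classes")
    X = np.stack([s.pixels.ravel() for s in samples])
    y = np.array([s.label for s in samples])
    if estimator is None:
        from sklearn.neural_network import MLPClassifier

        estimator = MLPClassifier(
            hidden_layer_sizes=cfg.hidden_layer_sizes,
            solver=cfg.optimizer if cfg.optimizer in ("adam", "sgd") else "adam",
            learning_rate_init=cfg.learning_rate,
            batch_size=min(cfg.batch_size, len(y)),
            max_iter=cfg.epochs,
            shuffle=True,
            random_state=cfg.seed,
        )
    with warnings.catch_warnings():
        # a fixed epoch budget is intentional; convergence warnings are noise
        from sklearn.exceptions import ConvergenceWarning
        warnings.simplefilter("ignore", ConvergenceWarning)
        estimator.fit(X, y)
    return GlyphModel(estimator, cfg)


def evaluate(model: GlyphModel, samples: Sequence[GlyphSample],
             ) -> tuple[float, np.ndarray]:
    """(accuracy, 3x3 confusion matrix).  Rows are true labels in the
    order (m, mu, other); accuracy is the trace over the total."""
    if not samples:
        raise ValueError("cannot evaluate on an empty sample list")
    from sklearn.metrics import confusion_matrix

    X = np.stack([s.pixels.ravel() for s in samples])
    y_true = [s.label for s in samples]
    y_pred = model.estimator.predict(X)
    cm = confusion_matrix(y_true, y_pred, labels=list(LABELS))
    acc = float(np.trace(cm) / cm.sum())
    return acc, cm


def save_samples(samples: Sequence[GlyphSample], out_dir: str | Path) -> None:
    """Persist samples as PNG files plus a labels CSV."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        fname = f"glyph_{i:05d}.png"
        Image.fromarray(((1.0 - s.pixels) * 255).astype(np.uint8)).save(out / fname)
        rows.append({"file": fname, "label": s.label, **s.meta})
    pd.DataFrame(rows).to_csv(out / "labels.csv", index=False)
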