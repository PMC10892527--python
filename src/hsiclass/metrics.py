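"""Accuracy assessment: confusion matrices, OA/AA/kappa, PA/UA, map rendering.

Matrix orientation follows the remote-sensing accuracy-assessment tables this
package reproduces: rows are the reference (true) class, columns the
predicted class, producer's accuracy (PA) runs along rows and user's accuracy
(UA) along columns.  The literature is split on this orientation, so it is
fixed here explicitly.  Per-class values for empty rows/columns are reported
as missing (NaN), never as zero, and are excluded from the average accuracy.

Percentages are reported at two decimals with round-half-away-from-zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import LabelMap
from .exceptions import SizeError
from .preprocess import PatchDataset, extract_patches

__all__ = [
    "ConfusionMatrix", "MetricsReport", "confusion_matrix",
    "classwise_accuracy", "summary_metrics", "build_report",
    "round_half_away", "classify_scene", "render_classification_map",
    "colorize_labels",
]


def round_half_away(x, decimals: int = 2):
    """Round half away from zero (table convention), elementwise."""
    x = np.asarray(x, dtype=float)
    factor = 10.0 ** decimals
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return float(out) if out.ndim == 0 else out


@dataclass
class ConfusionMatrix:
    """K x K reference-by-predicted counts."""

    counts: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise SizeError("confusion matrix must be square")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.round(self.counts)):
                raise SizeError("confusion counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise SizeError("confusion counts must be non-negative")
        if not self.class_names:
            self.class_names = [f"class {i + 1}" for i in range(len(self.counts))]

    @property
    def K(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(y_true, y_pred, K: int,
                     class_names: list[str] | None = None) -> ConfusionMatrix:
    """Tally counts[i][j] = #{true == i+1 and pred == j+1}; ids are 1..K."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise SizeError("y_true and y_pred lengths differ")
    if y_true.size and (y_true.min() < 1 or y_true.max() > K
                        or y_pred.min() < 1 or y_pred.max() > K):
        raise SizeError(f"class ids must lie in 1..{K}")
    counts = np.zeros((K, K), dtype=np.int64)
    np.add.at(counts, (y_true - 1, y_pred - 1), 1)
    return ConfusionMatrix(counts, class_names or [])


def classwise_accuracy(cm: ConfusionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Producer's and user's accuracy in percent; NaN where undefined."""
    counts = cm.counts.astype(float)
    diag = np.diag(counts)
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = np.where(row > 0, 100.0 * diag / row, np.nan)
        ua = np.where(col > 0, 100.0 * diag / col, np.nan)
    if np.isnan(pa).any() or np.isnan(ua).any():
        warnings.warn("empty reference or prediction class: per-class accuracy "
                      "undefined for some classes", stacklevel=2)
    return pa, ua


def summary_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(OA %, AA %, kappa).

    OA = 100 * trace / total; AA = unweighted mean of the defined PA values;
    kappa = (p_o - p_e) / (1 - p_e) with p_e = sum_i row_i * col_i / total^2.
    """
    total = cm.total
    if total == 0:
        raise SizeError("cannot score an empty confusion matrix")
    counts = cm.counts.astype(float)
    p_o = np.trace(counts) / total
    oa = 100.0 * p_o
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pa, _ = classwise_accuracy(cm)
    aa = float(np.nanmean(pa))
    p_e = float((counts.sum(axis=1) * counts.sum(axis=0)).sum()) / total ** 2
    kappa = 1.0 if p_e == 1.0 and p_o == 1.0 else (p_o - p_e) / (1.0 - p_e)
    return float(oa), aa, float(kappa)


@dataclass
class MetricsReport:
    """Full accuracy report for one evaluation."""

    oa: float
    aa: float
    kappa: float
    pa: np.ndarray
    ua: np.ndarray
    cm: ConfusionMatrix

    def rounded(self) -> dict:
        return {
            "OA": round_half_away(self.oa),
            "AA": round_half_away(self.aa),
            "kappa": round_half_away(self.kappa, 3),
            "PA": [None if np.isnan(v) else round_half_away(v) for v in self.pa],
            "UA": [None if np.isnan(v) else round_half_away(v) for v in self.ua],
        }

    def to_dict(self) -> dict:
        d = self.rounded()
        d["confusion_matrix"] = self.cm.counts.tolist()
        d["class_names"] = list(self.cm.class_names)
        return d

    def summary(self) -> str:
        names = self.cm.class_names
        width = max(14, max((len(n) for n in names), default=0) + 2)
        lines = [f"Overall accuracy (OA):  {self.oa:6.2f} %",
                 f"Average accuracy (AA):  {self.aa:6.2f} %",
                 f"Kappa coefficient:      {self.kappa:6.3f}",
                 "",
                 "Reference \\ predicted".ljust(width)
                 + "".join(n[:width - 1].rjust(width) for n in names)
                 + "PA (%)".rjust(10)]
        for i, name in enumerate(names):
            pa = "  n/a" if np.isnan(self.pa[i]) else f"{self.pa[i]:.2f}"
            lines.append(name.ljust(width)
                         + "".join(str(v).rjust(width) for v in self.cm.counts[i])
                         + pa.rjust(10))
        ua_row = "UA (%)".ljust(width) + "".join(
            ("n/a" if np.isnan(v) else f"{v:.2f}").rjust(width) for v in self.ua)
        lines.append(ua_row)
        return "\n".join(lines)


def build_report(cm: ConfusionMatrix) -> MetricsReport:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pa, ua = classwise_accuracy(cm)
    oa, aa, kappa = summary_metrics(cm)
    return MetricsReport(oa, aa, kappa, pa, ua, cm)


# ---------------------------------------------------------------------------
# Classification maps
# ---------------------------------------------------------------------------

def classify_scene(model, scores: np.ndarray, S: int,
                   scaler=None, pad_mode: str = "reflect",
                   batch_size: int = 512) -> np.ndarray:
    """Classify every pixel of a reduced scene; returns an (H, W) id raster.

    Each pixel is scored from its own S x S x B patch, exactly the path used
    for the labeled samples during evaluation.
    """
    h, w, _ = scores.shape
    all_labeled = LabelMap(np.ones((h, w), dtype=np.int32))
    ds = extract_patches(scores, all_labeled, S, pad_mode)
    patches = scaler.apply(ds).patches if scaler is not None else ds.patches
    pred = model.predict(patches, batch_size=batch_size)
    out = np.zeros((h, w), dtype=np.int32)
    out[ds.coords[:, 0], ds.coords[:, 1]] = pred
    return out


def colorize_labels(labels: np.ndarray, palette: dict) -> np.ndarray:
    """Map an (H, W) id raster to (H, W, 3) uint8 via {id: '#rrggbb'}."""
    present = np.unique(labels)
    missing = [int(c) for c in present if c != 0 and int(c) not in palette]
    if missing:
        raise SizeError(f"palette missing classes {missing}")
    rgb = np.zeros((*labels.shape, 3), dtype=np.uint8)
    for cid, color in palette.items():
        hexc = (color.get("color") if isinstance(color, dict) else color).lstrip("#")
        rgb[labels == cid] = [int(hexc[i:i + 2], 16) for i in (0, 2, 4)]
    return rgb


def render_classification_map(model, scores: np.ndarray, S: int, palette: dict,
                              scaler=None, background_mask: np.ndarray | None = None
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Full-scene classification map: (id raster, RGB image).

    ``background_mask`` (True = unlabeled background) optionally zeroes those
    pixels in the rendered raster.
    """
    labels = classify_scene(model, scores, S, scaler=scaler)
    if background_mask is not None:
        labels = np.where(background_mask, 0, labels)
    return labels, colorize_labels(labels, palette)
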