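"""Dense-block CNN classifier over 32x32x3 cell-image stacks.

The classifier turns de-novo cluster IDs into a reusable, transferable cell
classifier: it trains on (image, cluster-id) pairs from one experiment and
assigns events from later experiments to those classes with a per-event
probability vector.

Architecture: three dense blocks take the 32x32x3 input (BF, SSC, DNA) to a
final 4x4x87 feature map.  Inside a block each of three 3x3 convolutions
receives the concatenation of the block input and all previous layer
outputs (dense connectivity), each followed by a leaky ReLU; the block ends
with a 3x3 stride-2 convolution halving width and height and setting the
transition channel count (22, 44, 87).  The final 4*4*87 = 1392 vector is
fully connected to the class logits.  Training minimizes softmax
cross-entropy plus L2 weight decay with Adam and a stepwise-decaying
learning rate.

The network, its backward pass and the Adam optimizer are implemented
directly on numpy arrays (im2col convolutions); everything runs on a single
CPU and is deterministic for a fixed seed on one platform.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

log = logging.getLogger(__name__)

FLATTEN_LENGTH = 4 * 4 * 87
DEFAULT_CHANNEL_ORDER = ("BF", "SSC", "DNA")


@dataclass
class ClassifierConfig:
    """Training hyper-parameters; defaults follow the pipeline's protocol."""

    input_size: tuple[int, int, int] = (32, 32, 3)
    growth_rate: int = 4
    transition_channels: tuple[int, int, int] = (8, 16, 87)
    leaky_slope: float = 0.1
    l2: float = 1e-4
    learning_rate: float = 1e-3
    lr_decay: float = 0.99
    lr_decay_interval: int = 100
    iterations: int = 25_000
    batch_size: int = 256
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    eval_interval: int = 100
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.transition_channels[-1] != 87:
            raise ValueError("final transition must have 87 feature maps")
        if tuple(self.input_size) != (32, 32, 3):
            raise ValueError("input must be 32x32x3")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


# ---------------------------------------------------------------------------
# image preparation

def crop_pad_32(stack: np.ndarray) -> np.ndarray:
    """Center-crop or symmetric zero-pad an (H, W, C) stack to 32x32xC.

    Cropping takes the center 32 rows/cols (start = (n-32)//2); padding puts
    the extra pixel on the trailing side when the deficit is odd.  Channels
    are handled identically.
    """
    if stack.ndim == 2:
        stack = stack[:, :, None]
    h, w, c = stack.shape
    out = stack
    for axis, n in ((0, h), (1, w)):
        if n > 32:
            start = (n - 32) // 2
            out = out.take(range(start, start + 32), axis=axis)
        elif n < 32:
            before = (32 - n) // 2
            after = 32 - n - before
            pads = [(0, 0)] * 3
            pads[axis] = (before, after)
            out = np.pad(out, pads)
    return out


def prepare_stacks(events, channel_order=DEFAULT_CHANNEL_ORDER) -> np.ndarray:
    """Stack events into an (N, 32, 32, C) float32 array, crop/padded."""
    return np.stack([crop_pad_32(ev.stack(list(channel_order))) for ev in events]
                    ).astype(np.float32)


# ---------------------------------------------------------------------------
# label handling

def merge_classes(cluster_ids, merge_map: dict | None = None):
    """Map de-novo cluster ids onto training class ids.

    ``merge_map`` sends original cluster id -> class label and must cover
    every observed id; ``None`` means the identity map.  Returns
    ``(class_index array, class_labels list)`` where class indices are
    0-based in sorted label order.
    """
    ids = np.asarray(cluster_ids)
    if merge_map is None:
        merge_map = {c: c for c in np.unique(ids)}
    unmapped = set(np.unique(ids)) - set(merge_map)
    if unmapped:
        raise ValueError(f"cluster ids without a class mapping: {sorted(unmapped)}")
    labels = sorted(set(merge_map[c] for c in np.unique(ids)), key=str)
    index = {lab: i for i, lab in enumerate(labels)}
    return np.array([index[merge_map[c]] for c in ids], dtype=np.int64), labels


def split_dataset(labels, fractions=(0.8, 0.1, 0.1), seed: int = 0):
    """Stratified-by-class random split into (train, test, validate) indices."""
    labels = np.asarray(labels)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    train, test, val = [], [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) < 3:
            raise ValueError(f"class {c} has fewer than 3 events")
        idx = rng.permutation(idx)
        n = len(idx)
        n_tr = int(round(fractions[0] * n))
        n_te = int(round(fractions[1] * n))
        n_tr = min(n_tr, n - 2)
        n_te = max(1, min(n_te, n - n_tr - 1))
        train.append(idx[:n_tr])
        test.append(idx[n_tr:n_tr + n_te])
        val.append(idx[n_tr + n_te:])
    return (np.sort(np.concatenate(train)), np.sort(np.concatenate(test)),
            np.sort(np.concatenate(val)))


# ---------------------------------------------------------------------------
# network internals (numpy, NHWC, float32)
#
# Convolutions are im2col + GEMM.  The im2col buffers (the dominant memory
# traffic) live in a per-layer workspace that is reused across iterations:
# repeated large allocations would re-fault pages every step, which on a
# single CPU costs more than the GEMMs themselves.

def _ws_get(ws: dict | None, key, shape, dtype):
    if ws is None:
        return np.zeros(shape, dtype=dtype)
    buf = ws.get(key)
    if buf is None or buf.shape != shape or buf.dtype != dtype:
        buf = np.zeros(shape, dtype=dtype)
        ws[key] = buf
    return buf


def _tap_buffers(x: np.ndarray, stride: int, ws: dict | None, key):
    """Gather the nine 3x3 taps of a same-padded input into a (9, N, Ho, Wo,
    C) buffer (contiguous per tap, reused across iterations)."""
    n, h, w, c = x.shape
    hp, wp = h + 2, w + 2
    ho = (hp - 3) // stride + 1
    wo = (wp - 3) // stride + 1
    xp = _ws_get(ws, (key, "pad"), (n, hp, wp, c), x.dtype)
    xp[:, 1:-1, 1:-1, :] = x          # borders stay zero
    taps = _ws_get(ws, (key, "taps"), (9, n, ho, wo, c), x.dtype)
    for t in range(9):
        i, j = divmod(t, 3)
        np.copyto(taps[t], xp[:, i:i + stride * ho:stride,
                              j:j + stride * wo:stride, :])
    return taps, (n, ho, wo, c, hp, wp)


def _conv_forward(x, W, b, stride, ws=None, key=None):
    taps, info = _tap_buffers(x, stride, ws, key)
    n, ho, wo, c = info[0], info[1], info[2], info[3]
    m = n * ho * wo
    # batched GEMM over taps: (9, M, C) @ (9, C, Cout), summed over taps
    out = np.matmul(taps.reshape(9, m, c), W.reshape(9, c, -1)).sum(axis=0)
    out += b
    return out.reshape(n, ho, wo, -1), (taps, info)


def _conv_backward(dout, cache, W, stride, ws=None, key=None, need_dx=True):
    taps, (n, ho, wo, c, hp, wp) = cache
    m = n * ho * wo
    cout = dout.shape[-1]
    dflat = dout.reshape(m, cout)
    dW = np.matmul(taps.reshape(9, m, c).transpose(0, 2, 1),
                   np.broadcast_to(dflat, (9, m, cout))).reshape(9 * c, cout)
    db = dflat.sum(axis=0)
    if not need_dx:
        return None, dW, db
    if stride == 1:
        # input gradient of a same-padded 3x3 conv is itself a 3x3 conv of
        # dout with the spatially rotated, transposed kernel
        rot = np.ascontiguousarray(
            W.reshape(3, 3, c, cout)[::-1, ::-1].transpose(0, 1, 3, 2)
        ).reshape(9, cout, c)
        dtaps, _ = _tap_buffers(dout, 1, ws, (key, "dx"))
        dx = np.matmul(dtaps.reshape(9, m, cout), rot).sum(axis=0)
        return dx.reshape(n, ho, wo, c), dW, db
    # strided conv: scatter-add each tap's contribution into the padded grid
    dtaps = np.matmul(np.broadcast_to(dflat, (9, m, cout)),
                      W.reshape(9, c, cout).transpose(0, 2, 1))
    dtaps = dtaps.reshape(9, n, ho, wo, c)
    dxp = _ws_get(ws, (key, "dxp"), (n, hp, wp, c), dout.dtype)
    dxp[:] = 0
    for t in range(9):
        i, j = divmod(t, 3)
        dxp[:, i:i + stride * ho:stride, j:j + stride * wo:stride, :] += dtaps[t]
    return dxp[:, 1:-1, 1:-1, :].copy(), dW, db


def _lrelu(z, slope):
    return np.where(z > 0, z, slope * z)


def _lrelu_grad(z, slope):
    return np.where(z > 0, 1.0, slope).astype(z.dtype)


class DenseNetSmall:
    """Three dense blocks + FC head; explicit forward/backward on numpy."""

    def __init__(self, n_classes: int, config: ClassifierConfig):
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        self.n_classes = n_classes
        self.config = config
        self._ws: dict = {}          # reused im2col / padding buffers
        g = config.growth_rate
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, np.ndarray] = {}
        c_in = config.input_size[2]
        spatial = config.input_size[0]
        for bi, c_out in enumerate(config.transition_channels):
            c = c_in
            for li in range(3):
                self._add_conv(rng, f"b{bi}l{li}", c, g)
                c += g
            self._add_conv(rng, f"b{bi}t", c, c_out)
            c_in = c_out
            spatial //= 2
        assert spatial == 4 and c_in == 87
        self.flatten_length = spatial * spatial * c_in
        assert self.flatten_length == FLATTEN_LENGTH
        self.params["fc_W"] = (rng.standard_normal((self.flatten_length, n_classes))
                               * np.sqrt(2.0 / self.flatten_length)).astype(np.float32)
        self.params["fc_b"] = np.zeros(n_classes, dtype=np.float32)

    def _add_conv(self, rng, name, c_in, c_out):
        w = rng.standard_normal((9 * c_in, c_out)) * np.sqrt(2.0 / (9 * c_in))
        self.params[f"{name}_W"] = w.astype(np.float32)
        self.params[f"{name}_b"] = np.zeros(c_out, dtype=np.float32)

    # ---- forward / backward -------------------------------------------
    def forward(self, x: np.ndarray, keep_cache: bool = False):
        slope = self.config.leaky_slope
        cache = {"blocks": []} if keep_cache else None
        h = x.astype(self.params["fc_W"].dtype, copy=False)
        for bi in range(3):
            feats = [h]
            bcache = {"convs": []}
            for li in range(3):
                inp = np.concatenate(feats, axis=-1) if len(feats) > 1 else feats[0]
                name = f"b{bi}l{li}"
                z, cc = _conv_forward(inp, self.params[f"{name}_W"],
                                      self.params[f"{name}_b"], 1,
                                      self._ws, name)
                feats.append(_lrelu(z, slope))
                if keep_cache:
                    bcache["convs"].append((name, cc, z, [f.shape[-1] for f in feats[:-1]]))
                else:
                    del cc
            inp = np.concatenate(feats, axis=-1)
            name = f"b{bi}t"
            z, cc = _conv_forward(inp, self.params[f"{name}_W"],
                                  self.params[f"{name}_b"], 2,
                                  self._ws, name)
            h = _lrelu(z, slope)
            if keep_cache:
                bcache["transition"] = (name, cc, z, [f.shape[-1] for f in feats])
                cache["blocks"].append(bcache)
        flat = h.reshape(len(h), -1)
        logits = flat @ self.params["fc_W"] + self.params["fc_b"]
        if keep_cache:
            cache["flat"] = flat
            cache["pre_flat_shape"] = h.shape
        return logits, cache

    def backward(self, dlogits: np.ndarray, cache) -> dict[str, np.ndarray]:
        slope = self.config.leaky_slope
        grads: dict[str, np.ndarray] = {}
        grads["fc_W"] = cache["flat"].T @ dlogits
        grads["fc_b"] = dlogits.sum(axis=0)
        dh = (dlogits @ self.params["fc_W"].T).reshape(cache["pre_flat_shape"])
        for bi in range(2, -1, -1):
            bcache = cache["blocks"][bi]
            name, cc, z, widths = bcache["transition"]
            dz = dh * _lrelu_grad(z, slope)
            dinp, dW, db = _conv_backward(dz, cc, self.params[f"{name}_W"], 2,
                                          self._ws, name)
            grads[f"{name}_W"], grads[f"{name}_b"] = dW, db
            dfeats = list(np.split(dinp, np.cumsum(widths)[:-1], axis=-1))
            for li in range(2, -1, -1):
                name, cc, z, widths = bcache["convs"][li]
                dz = dfeats[li + 1] * _lrelu_grad(z, slope)
                # the image gradient (block 0, layer 0) is never used
                need_dx = not (bi == 0 and li == 0)
                dinp, dW, db = _conv_backward(dz, cc, self.params[f"{name}_W"], 1,
                                              self._ws, name, need_dx=need_dx)
                grads[f"{name}_W"], grads[f"{name}_b"] = dW, db
                if need_dx:
                    for part, dpart in zip(
                            range(li + 1),
                            np.split(dinp, np.cumsum(widths)[:-1], axis=-1)):
                        dfeats[part] = dfeats[part] + dpart
            dh = dfeats[0]
        return grads


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class ClassifierModel:
    """Trained network + class labels + preprocessing spec + training log."""

    net: DenseNetSmall
    class_labels: list
    channel_order: tuple[str, ...] = DEFAULT_CHANNEL_ORDER
    channel_scale: np.ndarray | None = None    # per-channel divisor
    training_log: list[dict] = field(default_factory=list)

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    def _prep(self, stacks: np.ndarray) -> np.ndarray:
        x = np.asarray(stacks, dtype=np.float32)
        if x.ndim != 4 or x.shape[1:3] != (32, 32):
            raise ValueError(f"expected (N,32,32,C) stacks, got {x.shape}")
        if x.shape[3] != len(self.channel_order):
            raise ValueError(f"channel mismatch: model expects {self.channel_order}")
        if self.channel_scale is not None:
            x = x / self.channel_scale.astype(np.float32)
        return x

    def predict_proba(self, stacks: np.ndarray, chunk: int = 512) -> np.ndarray:
        x = self._prep(stacks)
        out = []
        for i in range(0, len(x), chunk):
            logits, _ = self.net.forward(x[i:i + chunk])
            out.append(_softmax(logits))
        return np.concatenate(out) if out else np.zeros((0, self.n_classes))

    def save(self, weights_path, meta_path) -> None:
        np.savez(weights_path, **self.net.params)
        meta = {
            "class_labels": list(map(str, self.class_labels)),
            "channel_order": list(self.channel_order),
            "channel_scale": (None if self.channel_scale is None
                              else self.channel_scale.tolist()),
            "config": asdict(self.net.config),
            "n_classes": self.n_classes,
            "training_log": self.training_log,
        }
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, weights_path, meta_path) -> "ClassifierModel":
        with open(meta_path) as fh:
            meta = json.load(fh)
        cfg = ClassifierConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                                  for k, v in meta["config"].items()})
        net = DenseNetSmall(meta["n_classes"], cfg)
        with np.load(weights_path) as z:
            net.params = {k: z[k] for k in z.files}
        scale = meta["channel_scale"]
        return cls(net, meta["class_labels"], tuple(meta["channel_order"]),
                   None if scale is None else np.asarray(scale, dtype=np.float32),
                   meta["training_log"])


def build_network(n_classes: int, config: ClassifierConfig | None = None) -> ClassifierModel:
    """Construct the untrained classifier; asserts the architecture constants
    (flatten length 1392, final 4x4x87) at build time."""
    config = config or ClassifierConfig()
    net = DenseNetSmall(n_classes, config)
    return ClassifierModel(net, class_labels=list(range(n_classes)))


# ---------------------------------------------------------------------------
# training

def _loss_and_grads(net: DenseNetSmall, x, y, l2):
    logits, cache = net.forward(x, keep_cache=True)
    p = _softmax(logits)
    n = len(x)
    ce = -float(np.mean(np.log(np.maximum(p[np.arange(n), y], 1e-12))))
    reg = sum(float(np.sum(w.astype(np.float64) ** 2))
              for k, w in net.params.items() if k.endswith("_W"))
    dlogits = (p - np.eye(net.n_classes, dtype=np.float32)[y]) / n
    grads = net.backward(dlogits.astype(np.float32), cache)
    for k in grads:
        if k.endswith("_W"):
            grads[k] = grads[k] + 2.0 * l2 * net.params[k]
    acc = float(np.mean(logits.argmax(axis=1) == y))
    return ce + l2 * reg, ce, acc, grads


def train(model: ClassifierModel, train_images: np.ndarray, train_labels: np.ndarray,
          test_images: np.ndarray, test_labels: np.ndarray,
          config: ClassifierConfig | None = None) -> ClassifierModel:
    """Train with Adam on softmax cross-entropy + L2.

    Batches of ``batch_size`` are sampled with replacement each iteration;
    the learning rate is ``learning_rate * lr_decay**(iter//interval)``.
    Test loss and accuracy are recorded every ``eval_interval`` iterations;
    a divergence warning is emitted when test loss rises >20% above its
    running minimum while train loss keeps falling.  Raises on NaN loss.
    """
    cfg = config or model.net.config
    net = model.net
    if set(np.unique(test_labels)) - set(np.unique(train_labels)):
        raise ValueError("test set contains classes absent from training set")
    scale = np.percentile(train_images.reshape(-1, train_images.shape[3]), 99.5, axis=0)
    model.channel_scale = np.maximum(scale, 1e-6).astype(np.float32)
    xtr = model._prep(train_images)
    xte = model._prep(test_images)
    rng = np.random.default_rng(cfg.seed + 1)
    m = {k: np.zeros_like(v) for k, v in net.params.items()}
    v = {k: np.zeros_like(vv) for k, vv in net.params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    model.training_log = []
    min_test_loss = np.inf
    prev_train_loss = np.inf
    for it in range(1, cfg.iterations + 1):
        batch = rng.integers(0, len(xtr), size=cfg.batch_size)
        loss, ce, acc, grads = _loss_and_grads(net, xtr[batch], train_labels[batch], cfg.l2)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"NaN/inf loss at iteration {it}; last train acc {acc:.3f}")
        lr = cfg.learning_rate * cfg.lr_decay ** (it // cfg.lr_decay_interval)
        for k, gk in grads.items():
            m[k] = b1 * m[k] + (1 - b1) * gk
            v[k] = b2 * v[k] + (1 - b2) * gk * gk
            mhat = m[k] / (1 - b1 ** it)
            vhat = v[k] / (1 - b2 ** it)
            net.params[k] = (net.params[k] - lr * mhat / (np.sqrt(vhat) + eps)
                             ).astype(np.float32)
        if it % cfg.eval_interval == 0:
            te_loss, te_acc = _eval_loss_acc(model, xte, test_labels, cfg.l2)
            model.training_log.append({
                "iteration": it, "learning_rate": lr,
                "train_loss": float(loss), "train_acc": acc,
                "test_loss": te_loss, "test_acc": te_acc,
            })
            if te_loss < min_test_loss:
                min_test_loss = te_loss
            elif (te_loss > 1.2 * min_test_loss and loss < prev_train_loss):
                warnings.warn(f"iteration {it}: test loss {te_loss:.3f} is >20% above "
                              f"its minimum {min_test_loss:.3f} while train loss falls "
                              "— training and test trends diverge (possible memorization)")
            prev_train_loss = loss
            log.info("iter %d: train loss %.4f acc %.3f | test loss %.4f acc %.3f",
                     it, loss, acc, te_loss, te_acc)
    return model


def _eval_loss_acc(model: ClassifierModel, x_prepped, y, l2, chunk: int = 512):
    ce_sum, correct = 0.0, 0
    for i in range(0, len(x_prepped), chunk):
        logits, _ = model.net.forward(x_prepped[i:i + chunk])
        p = _softmax(logits)
        yy = y[i:i + chunk]
        ce_sum += -float(np.sum(np.log(np.maximum(p[np.arange(len(yy)), yy], 1e-12))))
        correct += int(np.sum(logits.argmax(axis=1) == yy))
    reg = sum(float(np.sum(w.astype(np.float64) ** 2))
              for k, w in model.net.params.items() if k.endswith("_W"))
    return ce_sum / len(y) + l2 * reg, correct / len(y)


# ---------------------------------------------------------------------------
# evaluation & inference

def evaluate(model: ClassifierModel, images: np.ndarray, labels: np.ndarray) -> dict:
    """Validation metrics: per-class precision/recall/f1, weighted f1,
    confusion matrix and per-event true-match probability (the softmax
    probability assigned to the event's original class)."""
    from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
    probs = model.predict_proba(images)
    preds = probs.argmax(axis=1)
    present = np.arange(model.n_classes)
    prec, rec, f1, support = precision_recall_fscore_support(
        labels, preds, labels=present, zero_division=np.nan)
    weighted_f1 = float(np.nansum(f1 * support) / support.sum())
    return {
        "accuracy": float(np.mean(preds == labels)),
        "precision": prec, "recall": rec, "f1": f1, "support": support,
        "weighted_f1": weighted_f1,
        "confusion": confusion_matrix(labels, preds, labels=present),
        "true_match_probability": probs[np.arange(len(labels)), labels],
    }


def classify(model: ClassifierModel, stacks: np.ndarray,
             reliability_threshold: float = 0.5) -> dict:
    """Assign new image stacks to classes.

    Returns probability vectors (each sums to 1 within 1e-6), argmax classes,
    max probabilities and a reliability report: the fraction of events whose
    max probability exceeds 0.5, flagged when below ``reliability_threshold``.
    """
    probs = model.predict_proba(stacks)
    argmax = probs.argmax(axis=1)
    maxp = probs.max(axis=1)
    frac = float(np.mean(maxp > 0.5)) if len(maxp) else 1.0
    report = {"fraction_confident": frac, "flagged": frac < reliability_threshold}
    if report["flagged"]:
        warnings.warn(f"only {frac:.1%} of events classified with max "
                      "probability > 0.5 — classifier may not transfer to this data")
    return {
        "probabilities": probs,
        "classes": np.array([model.class_labels[i] for i in argmax]),
        "max_probability": maxp,
        "reliability": report,
    }
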