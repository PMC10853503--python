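"""Self-distillation (DINO-style) training around the clustering backbone.

A student and an EMA teacher share the encoder architecture plus a 3-layer
projection head with an L2-normalized bottleneck and a final linear map to K
prototype logits. Each source tile yields a few large "global" views and
several small "local" views (multi-crop). The teacher sees globals only; its
logits are centered (running mean subtraction) and sharpened (low
temperature) into target distributions. The objective sums, over every
(global, local) pair, the cross-entropy between the teacher's target and the
student's tempered softmax; gradients flow into the student only and the
teacher follows as an exponential moving average,

    theta_t <- lambda * theta_t + (1 - lambda) * theta_s.

By default only teacher-global / student-local pairs enter the loss; an
opt-in flag adds the cross-global (g != g') pairs, which is required when no
local views are used. The loss is averaged (not summed) over pairs so its
magnitude is comparable across local-view counts.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy import ndimage

from . import backbone as bb
from .autodiff import Tensor, gelu, log_softmax, matmul

__all__ = [
    "SSLConfig",
    "ViewSet",
    "DistillState",
    "multi_crop",
    "init_head",
    "head_forward",
    "teacher_distribution",
    "dino_loss",
    "ema_update",
    "update_center",
    "AdamW",
    "train",
    "TrainResult",
    "save_checkpoint",
    "load_checkpoint",
]


# ----------------------------------------------------------------- config
@dataclass
class SSLConfig:
    """Training hyperparameters.

    Temperatures, centering momentum and the EMA ramp follow the standard
    self-distillation conventions (student temp 0.1, teacher temp 0.04,
    center momentum 0.9, lambda cosine-ramped 0.996 -> 1). Optimizer and
    schedule settings are conventional, not from any reference experiment.
    """

    n_global: int = 2
    n_local: int = 2
    global_size: int = 224
    local_size: int = 96
    global_scale_range: tuple = (0.4, 1.0)
    local_scale_range: tuple = (0.05, 0.4)
    out_dim: int = 4096  # K, prototype count
    head_hidden: int = 2048
    head_bottleneck: int = 256
    student_temperature: float = 0.1
    teacher_temperature: float = 0.04
    center_momentum: float = 0.9
    ema_base: float = 0.996
    ema_final: float = 1.0
    teacher_temperature_warmup: float | None = None  # start value, ramps to final
    teacher_temp_warmup_frac: float = 0.3
    warm_start_center: bool = True  # estimate the center before step 0
    freeze_last_epochs: int = 1  # epochs with the prototype layer frozen
    norm_last_layer: bool = True  # keep prototype columns unit-norm
    cross_global_terms: bool = False
    epochs: int = 5
    batch_size: int = 16
    lr: float = 1e-3
    weight_decay: float = 0.04
    warmup_frac: float = 0.1
    grad_clip: float = 3.0

    def __post_init__(self):
        if self.n_global < 1:
            raise ValueError("need at least one global view")
        if self.n_local < 0:
            raise ValueError("n_local must be >= 0")
        for r in (self.global_scale_range, self.local_scale_range):
            lo, hi = r
            if not (0 < lo <= hi <= 1):
                raise ValueError(f"scale range {r} outside (0, 1]")
        if self.student_temperature <= 0 or self.teacher_temperature <= 0:
            raise bb.ConfigError("temperatures must be positive")
        if not 0 <= self.center_momentum <= 1:
            raise ValueError("center momentum outside [0, 1]")

    @classmethod
    def tiny(cls) -> "SSLConfig":
        """Desk-scale companion to ``BackboneConfig.tiny`` (64 px tiles).

        Short runs need the study conditions rescaled: the EMA coefficient is
        held constant (a ramp to 1 would freeze the teacher mid-run), the
        sharpening temperature is matched to the smaller logit spread of a
        d=64 encoder, and crop scales are enlarged so a local view of a 64 px
        tile still carries the tile's phenotype."""
        return cls(global_size=64, local_size=32, out_dim=256,
                   head_hidden=256, head_bottleneck=64,
                   teacher_temperature=0.01,
                   ema_base=0.996, ema_final=0.996,
                   global_scale_range=(0.7, 1.0),
                   local_scale_range=(0.15, 0.5))

    def to_yaml(self, path):
        d = asdict(self)
        d["global_scale_range"] = list(self.global_scale_range)
        d["local_scale_range"] = list(self.local_scale_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "SSLConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for k in ("global_scale_range", "local_scale_range"):
            if k in raw:
                raw[k] = tuple(raw[k])
        return cls(**raw)


@dataclass
class ViewSet:
    """Augmented views of one source tile (globals first, then locals)."""

    global_views: list
    local_views: list
    source_id: str = ""

    def __post_init__(self):
        if len(self.global_views) < 1:
            raise ValueError("a view set needs at least one global view")


@dataclass
class DistillState:
    """Paired student/teacher parameters plus centering state."""

    student: dict  # name -> Tensor (requires_grad)
    teacher: dict  # name -> np.ndarray
    center: np.ndarray  # (K,)
    ema_coefficient: float
    student_temperature: float
    teacher_temperature: float
    center_momentum: float

    def __post_init__(self):
        if set(self.student) != set(self.teacher):
            raise ValueError("student/teacher parameter sets differ")
        for k, v in self.student.items():
            if v.data.shape != self.teacher[k].shape:
                raise ValueError(f"shape mismatch for parameter {k!r}")
        self.center = np.asarray(self.center, dtype=np.float64)


# ------------------------------------------------------------- multi-crop
def _resize(img: np.ndarray, size: int) -> np.ndarray:
    h, w = img.shape[:2]
    if h == size and w == size:
        return img
    return ndimage.zoom(
        img, (size / h, size / w, 1), order=1, grid_mode=True, mode="nearest"
    )


def _random_resized_crop(img, size, scale_range, rng):
    h, w = img.shape[:2]
    area = h * w
    for _ in range(10):
        frac = rng.uniform(*scale_range)
        log_ratio = rng.uniform(math.log(3 / 4), math.log(4 / 3))
        ratio = math.exp(log_ratio)
        cw = int(round(math.sqrt(area * frac * ratio)))
        ch = int(round(math.sqrt(area * frac / ratio)))
        if 0 < cw <= w and 0 < ch <= h:
            top = rng.integers(0, h - ch + 1)
            left = rng.integers(0, w - cw + 1)
            return _resize(img[top : top + ch, left : left + cw], size)
    side = min(h, w)
    return _resize(img[:side, :side], size)


def _color_jitter(img, rng, strength=0.2):
    b = rng.uniform(1 - strength, 1 + strength)  # brightness
    c = rng.uniform(1 - strength, 1 + strength)  # contrast
    s = rng.uniform(1 - strength, 1 + strength)  # saturation
    out = img * b
    mean = out.mean()
    out = (out - mean) * c + mean
    gray = out.mean(axis=2, keepdims=True)
    out = gray + (out - gray) * s
    return np.clip(out, 0.0, 1.0)


def multi_crop(
    tile,
    n_global: int = 2,
    n_local: int = 2,
    global_scale_range=(0.4, 1.0),
    local_scale_range=(0.05, 0.4),
    seed=None,
    global_size: int = 224,
    local_size: int = 96,
    jitter: bool = True,
    source_id: str = "",
) -> ViewSet:
    """Generate ``n_global`` large and ``n_local`` small augmented views.

    Each view is a random-resized crop followed by a random horizontal flip
    and (optionally) brightness/contrast/saturation jitter. Reproducible
    under a fixed ``seed`` (an int or a ``numpy.random.Generator``).
    """
    if n_local < 0:
        raise ValueError("n_local must be >= 0")
    for r in (global_scale_range, local_scale_range):
        if not (0 < r[0] <= r[1] <= 1):
            raise ValueError(f"scale range {r} outside (0, 1]")
    img = np.asarray(tile, dtype=np.float64)
    if img.max() > 1.5:
        img = img / 255.0
    if min(img.shape[:2]) < max(global_size, local_size):
        raise ValueError("tile smaller than requested view size")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def one(size, scale_range):
        v = _random_resized_crop(img, size, scale_range, rng)
        if rng.random() < 0.5:
            v = v[:, ::-1].copy()
        if jitter:
            v = _color_jitter(v, rng)
        return v.astype(np.float32)

    return ViewSet(
        global_views=[one(global_size, global_scale_range) for _ in range(n_global)],
        local_views=[one(local_size, local_scale_range) for _ in range(n_local)],
        source_id=source_id,
    )


# ------------------------------------------------------------ projection head
def init_head(
    cfg: SSLConfig, embed_dim: int, rng: np.random.Generator, dtype=np.float32
) -> dict[str, Tensor]:
    """3-layer MLP head with L2-normalized bottleneck and linear output."""
    h, bott, k = cfg.head_hidden, cfg.head_bottleneck, cfg.out_dim
    p = {
        "head.w1": bb._trunc_normal(rng, (embed_dim, h)),
        "head.b1": np.zeros(h),
        "head.w2": bb._trunc_normal(rng, (h, h)),
        "head.b2": np.zeros(h),
        "head.w3": bb._trunc_normal(rng, (h, bott)),
        "head.b3": np.zeros(bott),
    }
    # last layer: unit-norm prototype columns over the normalized bottleneck,
    # so logits are O(1) and the sharpened teacher produces usable targets
    last = rng.normal(0.0, 1.0, size=(bott, k))
    p["head.last"] = last / np.linalg.norm(last, axis=0, keepdims=True)
    return {kk: Tensor(v.astype(dtype), requires_grad=True) for kk, v in p.items()}


def head_forward(x: Tensor, params: dict) -> Tensor:
    h = gelu(matmul(x, params["head.w1"]) + params["head.b1"])
    h = gelu(matmul(h, params["head.w2"]) + params["head.b2"])
    h = matmul(h, params["head.w3"]) + params["head.b3"]
    norm = ((h * h).sum(axis=-1, keepdims=True) + 1e-12).sqrt()
    h = h / norm
    return matmul(h, params["head.last"])


def encode_views(views: np.ndarray, backbone_cfg, params: dict) -> Tensor:
    """Backbone + head logits for a (B, H, W, 3) stack of views."""
    emb = bb.forward_features(views, backbone_cfg, params)
    return head_forward(emb, params)


# --------------------------------------------------------------- objectives
def teacher_distribution(logits, center, teacher_temperature: float) -> np.ndarray:
    """Centered, sharpened teacher target: softmax((logits - center) / tau_t)."""
    if teacher_temperature <= 0:
        raise bb.ConfigError("teacher temperature must be positive")
    z = (np.asarray(logits, dtype=np.float64) - np.asarray(center)) / teacher_temperature
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def dino_loss(
    teacher_global_logits,
    student_local_logits,
    state: DistillState,
    student_global_logits=None,
    cross_global: bool = False,
):
    """Mean cross-entropy over (teacher-global, student-view) pairs.

    ``teacher_global_logits``: (N_g, B, K) array. ``student_local_logits``:
    (N_l, B, K) Tensor or array. With ``cross_global`` the pairs (g, g'),
    g != g', on ``student_global_logits`` are added — required when
    N_l == 0, otherwise the objective is undefined.

    Returns a scalar Tensor (``.data`` for the float value); each pair's
    cross-entropy is bounded below by the teacher-distribution entropy.
    """
    t = np.asarray(teacher_global_logits, dtype=np.float64)
    if t.ndim == 2:
        t = t[None]
    n_g = t.shape[0]
    s_local = student_local_logits
    if s_local is not None and not isinstance(s_local, Tensor):
        s_local = Tensor(np.asarray(s_local))
    n_l = 0 if s_local is None else s_local.shape[0]
    if n_l == 0 and not cross_global:
        raise ValueError(
            "loss undefined: no local views and cross-global terms disabled"
        )
    p_t = teacher_distribution(t, state.center, state.teacher_temperature)
    terms = []
    if n_l > 0:
        logp = log_softmax(s_local * (1.0 / state.student_temperature), axis=-1)
        for g in range(n_g):
            for l in range(n_l):
                ce = -(Tensor(p_t[g]) * logp[l]).sum(axis=-1).mean()
                terms.append(ce)
    if cross_global:
        if student_global_logits is None:
            raise ValueError("cross_global requires student_global_logits")
        s_g = student_global_logits
        if not isinstance(s_g, Tensor):
            s_g = Tensor(np.asarray(s_g))
        logp_g = log_softmax(s_g * (1.0 / state.student_temperature), axis=-1)
        for g in range(n_g):
            for g2 in range(s_g.shape[0]):
                if g2 == g:
                    continue
                ce = -(Tensor(p_t[g]) * logp_g[g2]).sum(axis=-1).mean()
                terms.append(ce)
    total = terms[0]
    for term in terms[1:]:
        total = total + term
    return total * (1.0 / len(terms))


def ema_update(state: DistillState, lam: float | None = None) -> None:
    """In-place teacher <- lam * teacher + (1 - lam) * student (no gradient)."""
    lam = state.ema_coefficient if lam is None else lam
    if not 0 <= lam <= 1:
        raise ValueError(f"EMA coefficient {lam} outside [0, 1]")
    for k, t in state.teacher.items():
        s = state.student[k].data
        if t.shape != s.shape:
            raise ValueError(f"state corruption: shape mismatch for {k!r}")
        t *= lam
        t += (1.0 - lam) * s


def update_center(center, batch_teacher_logits, center_momentum: float) -> np.ndarray:
    """center <- m * center + (1 - m) * batch mean of teacher logits."""
    logits = np.asarray(batch_teacher_logits, dtype=np.float64)
    logits = logits.reshape(-1, logits.shape[-1])
    if logits.shape[0] == 0:
        raise ValueError("empty batch")
    if not 0 <= center_momentum <= 1:
        raise ValueError("center momentum outside [0, 1]")
    return center_momentum * np.asarray(center) + (1 - center_momentum) * logits.mean(0)


# ---------------------------------------------------------------- optimizer
class AdamW:
    """Decoupled weight-decay Adam over a dict of Tensors.

    Weight decay applies to matrices only (biases, gains, [cls] tokens and
    the center-bias vector gamma are exempt, the usual transformer practice).
    """

    def __init__(self, params: dict, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.04):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            update = (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
            if p.data.ndim >= 2 and self.wd > 0:
                p.data *= 1.0 - lr * self.wd
            p.data -= (lr * update).astype(p.data.dtype)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None


def _clip_grads(params: dict, max_norm: float) -> None:
    total = math.sqrt(
        sum(float((p.grad**2).sum()) for p in params.values() if p.grad is not None)
    )
    if total > max_norm > 0:
        scale = max_norm / (total + 1e-12)
        for p in params.values():
            if p.grad is not None:
                p.grad = p.grad * scale


def _lr_at(step, total, base_lr, warmup_frac):
    warmup = max(1, int(total * warmup_frac))
    if step < warmup:
        return base_lr * (step + 1) / warmup
    frac = (step - warmup) / max(1, total - warmup)
    return 0.1 * base_lr + 0.9 * base_lr * 0.5 * (1 + math.cos(math.pi * frac))


def _lambda_at(step, total, base, final):
    return final - (final - base) * 0.5 * (1 + math.cos(math.pi * step / max(1, total)))


# ------------------------------------------------------------------- train
@dataclass
class TrainResult:
    student: dict
    teacher: dict
    center: np.ndarray
    loss_trace: list
    lambda_trace: list
    backbone_cfg: bb.BackboneConfig
    ssl_cfg: SSLConfig
    student_history: list = field(default_factory=list)


def train(
    dataset,
    backbone_cfg: bb.BackboneConfig,
    ssl_cfg: SSLConfig,
    seed: int = 0,
    log_path=None,
    record_student_history: bool = False,
    ema_override: float | None = None,
) -> TrainResult:
    """Run the full self-distillation loop on a sequence of tiles.

    ``dataset`` yields RGB arrays (values in [0, 1]) or objects with an
    ``image`` attribute. Per step: multi-crop views, teacher forward on
    globals (no gradient), student forward on local views (plus globals when
    cross-global terms are on), cross-entropy loss, backprop into the
    student only, AdamW step, EMA teacher update, center update.

    ``ema_override`` pins lambda to a constant (useful for endpoint checks);
    ``record_student_history`` snapshots student parameters and lambda after
    every step so the teacher can be replay-verified against the EMA
    recursion. Reproducible under a fixed seed.
    """
    tiles = [np.asarray(getattr(t, "image", t), dtype=np.float32) for t in dataset]
    if not tiles:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(seed)
    # float64 parameters: the clustering logits are unbounded dot products
    # whose exp must stay positive for the column-normalized mean
    student = bb.init_params(backbone_cfg, rng, dtype=np.float64)
    student.update(init_head(ssl_cfg, backbone_cfg.embed_dim, rng, dtype=np.float64))
    teacher = {k: v.data.copy() for k, v in student.items()}
    state = DistillState(
        student=student,
        teacher=teacher,
        center=np.zeros(ssl_cfg.out_dim),
        ema_coefficient=ssl_cfg.ema_base,
        student_temperature=ssl_cfg.student_temperature,
        teacher_temperature=ssl_cfg.teacher_temperature,
        center_momentum=ssl_cfg.center_momentum,
    )
    if ssl_cfg.warm_start_center:
        # initialize the center at the teacher's marginal mean logit so the
        # first steps already see centered targets (no centering transient)
        warm_n = min(len(tiles), 32)
        warm_idx = rng.choice(len(tiles), warm_n, replace=False)
        warm_views = np.stack(
            [
                multi_crop(
                    tiles[i], 1, 0, ssl_cfg.global_scale_range,
                    ssl_cfg.local_scale_range, seed=rng,
                    global_size=ssl_cfg.global_size, local_size=ssl_cfg.local_size,
                ).global_views[0]
                for i in warm_idx
            ]
        )
        teacher_t = {k: Tensor(v) for k, v in state.teacher.items()}
        state.center = encode_views(warm_views, backbone_cfg, teacher_t).data.mean(0)
    opt = AdamW(student, lr=ssl_cfg.lr, weight_decay=ssl_cfg.weight_decay)
    n = len(tiles)
    steps_per_epoch = math.ceil(n / ssl_cfg.batch_size)
    total_steps = ssl_cfg.epochs * steps_per_epoch
    loss_trace, lambda_trace, history = [], [], []
    writer = None
    log_fh = None
    if log_path is not None:
        log_fh = open(log_path, "w", newline="")
        writer = csv.writer(log_fh)
        writer.writerow(["step", "epoch", "loss", "lr", "ema_lambda"])
    step = 0
    try:
        for epoch in range(ssl_cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n, ssl_cfg.batch_size):
                batch_idx = order[start : start + ssl_cfg.batch_size]
                views = [
                    multi_crop(
                        tiles[i],
                        ssl_cfg.n_global,
                        ssl_cfg.n_local,
                        ssl_cfg.global_scale_range,
                        ssl_cfg.local_scale_range,
                        seed=rng,
                        global_size=ssl_cfg.global_size,
                        local_size=ssl_cfg.local_size,
                    )
                    for i in batch_idx
                ]
                b = len(views)
                globals_stack = np.stack(
                    [v for vs in views for v in vs.global_views]
                )  # (B * n_g,...) grouped per tile
                teacher_t = {k: Tensor(v) for k, v in state.teacher.items()}
                t_logits = encode_views(globals_stack, backbone_cfg, teacher_t).data
                k_dim = t_logits.shape[-1]
                t_logits = t_logits.reshape(b, ssl_cfg.n_global, k_dim).transpose(
                    1, 0, 2
                )
                s_local = None
                if ssl_cfg.n_local > 0:
                    locals_stack = np.stack(
                        [v for vs in views for v in vs.local_views]
                    )
                    s_logits = encode_views(locals_stack, backbone_cfg, student)
                    s_local = s_logits.reshape((b, ssl_cfg.n_local, k_dim)).transpose(
                        (1, 0, 2)
                    )
                if ssl_cfg.teacher_temperature_warmup is not None:
                    warm = max(1, int(total_steps * ssl_cfg.teacher_temp_warmup_frac))
                    frac = min(1.0, step / warm)
                    state.teacher_temperature = (
                        ssl_cfg.teacher_temperature_warmup
                        + (ssl_cfg.teacher_temperature - ssl_cfg.teacher_temperature_warmup)
                        * frac
                    )
                s_global = None
                if ssl_cfg.cross_global_terms:
                    s_g = encode_views(globals_stack, backbone_cfg, student)
                    s_global = s_g.reshape((b, ssl_cfg.n_global, k_dim)).transpose(
                        (1, 0, 2)
                    )
                loss = dino_loss(
                    t_logits, s_local, state,
                    student_global_logits=s_global,
                    cross_global=ssl_cfg.cross_global_terms,
                )
                value = float(loss.data)
                if not np.isfinite(value):
                    raise RuntimeError(f"loss diverged (non-finite) at step {step}")
                opt.zero_grad()
                loss.backward()
                if epoch < ssl_cfg.freeze_last_epochs:
                    student["head.last"].grad = None
                _clip_grads(student, ssl_cfg.grad_clip)
                lr = _lr_at(step, total_steps, ssl_cfg.lr, ssl_cfg.warmup_frac)
                opt.step(lr=lr)
                if ssl_cfg.norm_last_layer:
                    w_last = student["head.last"].data
                    w_last /= np.linalg.norm(w_last, axis=0, keepdims=True)
                lam = (
                    ema_override
                    if ema_override is not None
                    else _lambda_at(step, total_steps, ssl_cfg.ema_base, ssl_cfg.ema_final)
                )
                ema_update(state, lam)
                state.center = update_center(
                    state.center, t_logits, ssl_cfg.center_momentum
                )
                loss_trace.append(value)
                lambda_trace.append(lam)
                if record_student_history:
                    history.append(
                        {k: v.data.astype(np.float64).copy() for k, v in student.items()}
                    )
                if writer is not None:
                    writer.writerow([step, epoch, value, lr, lam])
                step += 1
    finally:
        if log_fh is not None:
            log_fh.close()
    return TrainResult(
        student=student,
        teacher=state.teacher,
        center=state.center,
        loss_trace=loss_trace,
        lambda_trace=lambda_trace,
        backbone_cfg=backbone_cfg,
        ssl_cfg=ssl_cfg,
        student_history=history,
    )


# --------------------------------------------------------------- checkpoints
def save_checkpoint(path, result: TrainResult) -> None:
    arrays = {f"student.{k}": v.data for k, v in result.student.items()}
    arrays.update({f"teacher.{k}": v for k, v in result.teacher.items()})
    arrays["center"] = result.center
    arrays["loss_trace"] = np.asarray(result.loss_trace)
    np.savez(path, **arrays)


def load_checkpoint(path):
    """Returns (student params, teacher params, center, loss trace)."""
    with np.load(path) as npz:
        student = {
            k[len("student.") :]: Tensor(npz[k].copy(), requires_grad=True)
            for k in npz.files
            if k.startswith("student.")
        }
        teacher = {
            k[len("teacher.") :]: npz[k].copy()
            for k in npz.files
            if k.startswith("teacher.")
        }
        return student, teacher, npz["center"].copy(), list(npz["loss_trace"])
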