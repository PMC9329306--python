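"""The Sleep-CAM network: per-modality feature extractors and a CAM head.

Each modality block is conv(elu) -> conv(elu) -> max-pool -> layer-norm
(normalizing across the kernel axis). The three blocks must pool to equal
temporal lengths; their features are concatenated along the feature axis.
The assignment head is a linear convolution with one kernel per sleep stage
producing the class activation map (CAM), followed by global average
pooling (GAP) over time and a softmax. Because GAP is linear, the stage
probabilities are exactly the softmax of the time-mean of the CAM — the
map decomposes each decision over time.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .errors import ResolutionError, ShapeMismatch
from .io import STAGES
from .montage import EEG, EMG, EOG, MODALITY_COUNTS
from .nn import Adam, Conv1d, Elu, LayerNormKernels, MaxPool1d, softmax
from .preprocess import EPOCH_SAMPLES, EpochSet

MODALITIES = (EEG, EOG, EMG)


@dataclass(frozen=True)
class BlockConfig:
    """Hyper-parameters of one feature-extraction block."""

    conv1_kernels: int
    conv1_width: int
    conv2_kernels: int
    conv2_width: int
    pool_size: int


@dataclass(frozen=True)
class ModelConfig:
    """Full architecture description; weight shapes derive from this alone."""

    eeg: BlockConfig
    eog: BlockConfig
    emg: BlockConfig
    cam_kernel_width: int = 5
    n_stages: int = 5
    seed: int = 0

    def block(self, modality: str) -> BlockConfig:
        return {EEG: self.eeg, EOG: self.eog, EMG: self.emg}[modality]

    def pooled_length(self, modality: str) -> int:
        n = EPOCH_SAMPLES[modality]
        pool = self.block(modality).pool_size
        if n % pool:
            raise ShapeMismatch(
                f"{modality}: {n} samples not divisible by pool {pool}"
            )
        return n // pool

    def validate(self) -> None:
        lengths = {m: self.pooled_length(m) for m in MODALITIES}
        if len(set(lengths.values())) != 1:
            raise ShapeMismatch(f"unequal pooled lengths: {lengths}")
        for m in MODALITIES:
            b = self.block(m)
            for w in (b.conv1_width, b.conv2_width):
                if w % 2 != 1:
                    raise ShapeMismatch(f"{m}: kernel width {w} must be odd")
        if self.cam_kernel_width % 2 != 1:
            raise ShapeMismatch("cam_kernel_width must be odd")

    @property
    def cam_length(self) -> int:
        return self.pooled_length(EEG)

    @property
    def step_s(self) -> float:
        """Seconds of raw signal per CAM time step."""
        return 30.0 / self.cam_length

    def n_parameters(self) -> int:
        """Closed-form trainable parameter count."""
        total = 0
        n_features = 0
        for m in MODALITIES:
            b = self.block(m)
            cin = MODALITY_COUNTS[m]
            total += b.conv1_kernels * (cin * b.conv1_width) + b.conv1_kernels
            total += b.conv2_kernels * (b.conv1_kernels * b.conv2_width) + b.conv2_kernels
            total += 2 * b.conv2_kernels
            n_features += b.conv2_kernels
        total += self.n_stages * (n_features * self.cam_kernel_width) + self.n_stages
        return total


def default_config(seed: int = 0) -> ModelConfig:
    """Full-size architecture: kernel counts scale with the number of
    characteristic waves carried by each modality; pool sizes 20/10/20
    equalize the blocks at 300 steps (0.1 s per step)."""
    return ModelConfig(
        eeg=BlockConfig(64, 51, 64, 25, 20),
        eog=BlockConfig(32, 25, 32, 13, 10),
        emg=BlockConfig(16, 51, 16, 25, 20),
        cam_kernel_width=5,
        seed=seed,
    )


def reduced_config(seed: int = 0) -> ModelConfig:
    """Down-scaled architecture for CPU-budget experiments: same topology,
    fewer kernels, pool sizes 50/25/50 (120 steps, 0.25 s per step)."""
    return ModelConfig(
        eeg=BlockConfig(8, 25, 8, 13, 50),
        eog=BlockConfig(4, 13, 4, 7, 25),
        emg=BlockConfig(4, 25, 4, 13, 50),
        cam_kernel_width=5,
        seed=seed,
    )


@dataclass
class CamOutput:
    """Per-stage activation over time plus the stage confidence vector."""

    map: np.ndarray            # (5, T)
    step_s: float
    probabilities: np.ndarray  # (5,) simplex

    @property
    def logits(self) -> np.ndarray:
        return self.map.mean(axis=1)


class SleepCamModel:
    """A Sleep-CAM instance: configuration plus all trainable weights."""

    stage_order = STAGES

    def __init__(self, config: ModelConfig, dtype=np.float32):
        config.validate()
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(config.seed)
        self.blocks: dict[str, list] = {}
        n_features = 0
        for m in MODALITIES:
            b = config.block(m)
            cin = MODALITY_COUNTS[m]
            self.blocks[m] = [
                Conv1d(cin, b.conv1_kernels, b.conv1_width, rng, dtype=dtype),
                Elu(),
                Conv1d(b.conv1_kernels, b.conv2_kernels, b.conv2_width, rng, dtype=dtype),
                Elu(),
                MaxPool1d(b.pool_size),
                LayerNormKernels(b.conv2_kernels, dtype=dtype),
            ]
            n_features += b.conv2_kernels
        self.head = Conv1d(n_features, config.n_stages, config.cam_kernel_width,
                           rng, dtype=dtype)
        self._feature_splits = np.cumsum(
            [config.block(m).conv2_kernels for m in MODALITIES]
        )[:-1]

    # --- parameter plumbing -------------------------------------------
    def _layers(self):
        for m in MODALITIES:
            yield from self.blocks[m]
        yield self.head

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self._layers() for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self._layers() for g in layer.grads]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            if p.shape != w.shape:
                raise ShapeMismatch(f"weight shape {w.shape} != {p.shape}")
            p[...] = w

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params)

    # --- forward / backward -------------------------------------------
    def forward_batch(self, eeg: np.ndarray, eog: np.ndarray, emg: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
        """Return (cam, logits) for a batch; caches for backward()."""
        inputs = {EEG: eeg, EOG: eog, EMG: emg}
        feats = []
        for m in MODALITIES:
            x = np.asarray(inputs[m], dtype=self.dtype)
            want = (MODALITY_COUNTS[m], EPOCH_SAMPLES[m])
            if x.shape[1:] != want:
                raise ShapeMismatch(f"{m} block shape {x.shape[1:]}, expected {want}")
            for layer in self.blocks[m]:
                x = layer.forward(x)
            feats.append(x)
        features = np.concatenate(feats, axis=1)
        cam = self.head.forward(features)
        logits = cam.mean(axis=2)
        self._cam_t = cam.shape[2]
        return cam, logits

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate d(loss)/d(logits) through GAP and all blocks."""
        dcam = np.repeat(dlogits[:, :, None], self._cam_t, axis=2) / self._cam_t
        dfeat = self.head.backward(np.asarray(dcam, dtype=self.dtype))
        for m, dx in zip(MODALITIES, np.split(dfeat, self._feature_splits, axis=1)):
            d = np.ascontiguousarray(dx)
            for layer in reversed(self.blocks[m]):
                d = layer.backward(d)

    def forward(self, epochs: EpochSet, index: int | None = None):
        """CamOutput for one epoch (``index``) or a list for the whole set."""
        if index is not None:
            sub = epochs.subset([index])
        else:
            sub = epochs
        cam, logits = self.forward_batch(sub.eeg, sub.eog, sub.emg)
        probs = softmax(logits.astype(np.float64), axis=1)
        outs = [
            CamOutput(map=cam[i].astype(np.float64), step_s=self.config.step_s,
                      probabilities=probs[i])
            for i in range(cam.shape[0])
        ]
        return outs[0] if index is not None else outs

    def predict(self, epochs: EpochSet, batch_size: int = 256) -> np.ndarray:
        """Predicted stage labels for every epoch in the set."""
        out = []
        for lo in range(0, len(epochs), batch_size):
            sub = epochs.subset(range(lo, min(lo + batch_size, len(epochs))))
            _, logits = self.forward_batch(sub.eeg, sub.eog, sub.emg)
            out.append(np.argmax(logits, axis=1))
        idx = np.concatenate(out) if out else np.array([], dtype=int)
        return np.array([STAGES[i] for i in idx], dtype=object)

    def make_optimizer(self, lr: float) -> Adam:
        return Adam(self.params, lr)

    # --- persistence ---------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"param_{i}": p for i, p in enumerate(self.params)}
        np.savez(path, config=json.dumps(asdict(self.config)), **arrays)

    @classmethod
    def load(cls, path) -> "SleepCamModel":
        with np.load(path, allow_pickle=False) as data:
            cfg = json.loads(str(data["config"]))
            config = ModelConfig(
                eeg=BlockConfig(**cfg["eeg"]),
                eog=BlockConfig(**cfg["eog"]),
                emg=BlockConfig(**cfg["emg"]),
                cam_kernel_width=cfg["cam_kernel_width"],
                n_stages=cfg["n_stages"],
                seed=cfg["seed"],
            )
            model = cls(config)
            model.set_weights([data[f"param_{i}"] for i in range(len(model.params))])
        return model


#: alias matching the domain vocabulary: a model with weights
TrainedModel = SleepCamModel


def build_model(config: ModelConfig) -> SleepCamModel:
    """Construct an untrained Sleep-CAM with seeded He-normal weights."""
    return SleepCamModel(config)


def layer_normalize(features: np.ndarray) -> np.ndarray:
    """Standardize a (K, T) feature matrix across the kernel axis.

    Pre-affine layer normalization: at each time point the K feature values
    are shifted and scaled to mean 0, variance 1. The epsilon stabilizer
    only enters for (near-)constant columns, which map to all zeros, so the
    operation is exactly invariant to rescaling the input.
    """
    f = np.asarray(features, dtype=np.float64)
    if f.ndim != 2 or f.shape[0] < 2:
        raise ShapeMismatch("expected a (K>=2, T) feature matrix")
    mu = f.mean(axis=0, keepdims=True)
    var = f.var(axis=0, keepdims=True)
    denom = np.sqrt(np.where(var > 1e-30, var, var + 1e-10))
    return (f - mu) / denom


def predict_stage(cam: CamOutput) -> str:
    """Stage with maximal confidence; ties resolve to the earliest stage in
    the fixed order (W, REM, N1, N2, N3)."""
    return STAGES[int(np.argmax(cam.probabilities))]


def cam_to_half_second_bins(cam: CamOutput) -> np.ndarray:
    """Average the CAM into 60 half-second bins per stage (5 x 60).

    Requires the CAM step to divide 0.5 s evenly so bins align exactly.
    """
    per_bin = 0.5 / cam.step_s
    if abs(per_bin - round(per_bin)) > 1e-9:
        raise ResolutionError(f"step {cam.step_s} s does not divide 0.5 s")
    per_bin = int(round(per_bin))
    n_stages, t = cam.map.shape
    if t * cam.step_s != 30.0 and abs(t * cam.step_s - 30.0) > 1e-6:
        raise ResolutionError(f"CAM covers {t * cam.step_s} s, expected 30 s")
    return cam.map.reshape(n_stages, t // per_bin, per_bin).mean(axis=2)
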