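"""Modality-specific feature embeddings and imaging preprocessing.

Every feature becomes one fixed-length token of dimension ``d_model``:

* numerical  — a per-feature linear map, token = w_f * x + b_f;
* categorical — a per-feature lookup table (equivalent to one-hot times a
  matrix, but cheaper);
* imaging_embedding — a precomputed vector (length 256 by default) projected
  linearly to d_model.

Parameters are *per feature*, not per modality: the backbone uses no
positional encoding, so feature identity must live in the embedding itself.

The imaging pathway also ships the volume-side contract: `prepare_subvolume`
turns an arbitrary skull-stripped 3-D scan into a 128x128x128 intensity cube
in [0, 1] (resample -> foreground crop -> resize), and
`adapt_imaging_embedding` downsamples a 768x4x4x4 encoder output into a flat
256-vector through four convolutional blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, gather_rows
from .schema import FeatureSchema, FeatureSpec, Record, SchemaError, CodingError


@dataclass
class TokenSequence:
    """Per-record embedded tokens with a parallel presence mask."""

    tokens: np.ndarray  # (n_features, d_model)
    feature_names: list[str]
    presence: np.ndarray  # (n_features,) bool

    def __post_init__(self) -> None:
        if not (len(self.tokens) == len(self.feature_names) == len(self.presence)):
            raise ValueError("tokens, names and presence must have equal length")


class EmbeddingParams:
    """Per-feature embedding parameters plus the imaging adapter.

    ``numerical[name]`` is a dict with weight ``w`` and bias ``b`` (each
    length d_model); ``categorical[name]`` is a (cardinality, d_model) lookup
    table; ``imaging[name]`` is a (embed_dim, d_model) projection with bias.
    Standardization statistics (training-split mean/sd per numerical feature)
    are stored here so a saved model carries its own scaling.
    """

    def __init__(self, schema: FeatureSchema, d_model: int, rng: np.random.Generator):
        self.d_model = d_model
        self.numerical: dict[str, dict[str, Tensor]] = {}
        self.categorical: dict[str, Tensor] = {}
        self.imaging: dict[str, dict[str, Tensor]] = {}
        self.norm_stats: dict[str, tuple[float, float]] = {}  # name -> (mean, sd)
        scale = 1.0 / np.sqrt(d_model)
        for spec in schema:
            if spec.kind == "numerical":
                self.numerical[spec.name] = {
                    "w": Tensor(rng.normal(0, scale, d_model), requires_grad=True),
                    "b": Tensor(rng.normal(0, scale, d_model), requires_grad=True),
                }
            elif spec.kind == "categorical":
                self.categorical[spec.name] = Tensor(
                    rng.normal(0, scale, (len(spec.categories), d_model)),
                    requires_grad=True,
                )
            else:
                self.imaging[spec.name] = {
                    "w": Tensor(
                        rng.normal(0, 1.0 / np.sqrt(spec.embed_dim), (spec.embed_dim, d_model)),
                        requires_grad=True,
                    ),
                    "b": Tensor(np.zeros(d_model), requires_grad=True),
                }

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for d in self.numerical.values():
            out += [d["w"], d["b"]]
        out += list(self.categorical.values())
        for d in self.imaging.values():
            out += [d["w"], d["b"]]
        return out

    def l2_parameters(self) -> list[Tensor]:
        """Weights included in the explicit L2 term: matrices, not lookup
        rows or biases."""
        out: list[Tensor] = [d["w"] for d in self.numerical.values()]
        out += [d["w"] for d in self.imaging.values()]
        return out

    def standardize(self, name: str, x: float) -> float:
        mu, sd = self.norm_stats.get(name, (0.0, 1.0))
        return (x - mu) / sd


def embed_numerical(x: float, spec: FeatureSpec, params: EmbeddingParams) -> np.ndarray:
    """Linear token for a standardized numerical value: w_f * x + b_f."""
    if not np.isfinite(x):
        raise ValueError(f"non-finite value for numerical feature {spec.name!r}")
    p = params.numerical[spec.name]
    return p["w"].data * x + p["b"].data


def embed_categorical(code: str, spec: FeatureSpec, params: EmbeddingParams) -> np.ndarray:
    """Lookup-table row for a declared category code."""
    if code not in spec.categories:
        raise CodingError(f"feature {spec.name!r}: undeclared category {code!r}")
    row = spec.categories.index(code)
    return params.categorical[spec.name].data[row].copy()


def embed_imaging(vec: np.ndarray, spec: FeatureSpec, params: EmbeddingParams) -> np.ndarray:
    """Linear projection of a precomputed imaging-embedding vector."""
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (spec.embed_dim,):
        raise SchemaError(
            f"feature {spec.name!r}: embedding shape {vec.shape} != ({spec.embed_dim},)"
        )
    p = params.imaging[spec.name]
    return vec @ p["w"].data + p["b"].data


def assemble_tokens(
    record: Record, schema: FeatureSchema, params: EmbeddingParams
) -> TokenSequence:
    """One token per schema feature, in schema order.

    Absent features get presence=False and a zero token; their content is
    contractually irrelevant downstream (the attention mask blocks them).
    """
    d = params.d_model
    tokens = np.zeros((len(schema), d))
    presence = np.zeros(len(schema), dtype=bool)
    names = schema.names
    for fi, spec in enumerate(schema):
        if not record.observed.get(spec.name, False):
            continue
        presence[fi] = True
        v = record.values[spec.name]
        if spec.kind == "numerical":
            tokens[fi] = embed_numerical(params.standardize(spec.name, float(v)), spec, params)
        elif spec.kind == "categorical":
            tokens[fi] = embed_categorical(v, spec, params)
        else:
            tokens[fi] = embed_imaging(v, spec, params)
    return TokenSequence(tokens=tokens, feature_names=names, presence=presence)


# ---------------------------------------------------------------------------
# Batched embedding through the autograd graph (used by the model).


def batch_inputs(records: list[Record], schema: FeatureSchema, params: EmbeddingParams):
    """Precompute numpy arrays describing a batch for the autograd path.

    Returns (num_x, cat_idx, img_mats, presence): standardized numerical
    values (B, F_num) with zeros where missing, category row indices
    (B, F_cat), a dict name -> (B, embed_dim), and the presence matrix
    (B, n_features) in schema order.
    """
    B = len(records)
    num_specs = schema.features_of_kind("numerical")
    cat_specs = schema.features_of_kind("categorical")
    img_specs = schema.features_of_kind("imaging_embedding")

    num_x = np.zeros((B, len(num_specs)))
    cat_idx = np.zeros((B, len(cat_specs)), dtype=int)
    img_mats = {s.name: np.zeros((B, s.embed_dim)) for s in img_specs}
    presence = np.zeros((B, len(schema)), dtype=bool)

    order = {name: i for i, name in enumerate(schema.names)}
    for k, r in enumerate(records):
        for j, spec in enumerate(num_specs):
            if r.observed.get(spec.name, False):
                num_x[k, j] = params.standardize(spec.name, float(r.values[spec.name]))
                presence[k, order[spec.name]] = True
        for j, spec in enumerate(cat_specs):
            if r.observed.get(spec.name, False):
                cat_idx[k, j] = spec.categories.index(r.values[spec.name])
                presence[k, order[spec.name]] = True
        for spec in img_specs:
            if r.observed.get(spec.name, False):
                img_mats[spec.name][k] = r.values[spec.name]
                presence[k, order[spec.name]] = True
    return num_x, cat_idx, img_mats, presence


def embed_batch(
    num_x: np.ndarray,
    cat_idx: np.ndarray,
    img_mats: dict[str, np.ndarray],
    schema: FeatureSchema,
    params: EmbeddingParams,
) -> Tensor:
    """Token tensor (B, n_features, d_model) in schema order, on the tape."""
    from .autograd import concat

    B = num_x.shape[0]
    d = params.d_model
    num_specs = schema.features_of_kind("numerical")
    cat_specs = schema.features_of_kind("categorical")

    pieces: dict[str, Tensor] = {}
    if num_specs:
        W = concat(
            [params.numerical[s.name]["w"].reshape(1, d) for s in num_specs], axis=0
        )  # (F_num, d)
        Bb = concat([params.numerical[s.name]["b"].reshape(1, d) for s in num_specs], axis=0)
        x = Tensor(num_x[:, :, None])  # (B, F_num, 1)
        toks = x * W + Bb  # broadcast to (B, F_num, d)
        for j, s in enumerate(num_specs):
            pieces[s.name] = toks[:, j : j + 1, :]
    for j, s in enumerate(cat_specs):
        rows = gather_rows(params.categorical[s.name], cat_idx[:, j])  # (B, d)
        pieces[s.name] = rows.reshape(B, 1, d)
    for s in schema.features_of_kind("imaging_embedding"):
        p = params.imaging[s.name]
        proj = Tensor(img_mats[s.name]) @ p["w"] + p["b"]
        pieces[s.name] = proj.reshape(B, 1, d)

    return concat([pieces[name] for name in schema.names], axis=1)


# ---------------------------------------------------------------------------
# Imaging volume preprocessing and the encoder-output adapter.


def load_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI volume and its voxel spacing (mm) from the header.

    Orientation is assumed already standardized; registration is out of
    scope for this package.
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def prepare_subvolume(
    volume: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    target_spacing: float = 1.5,
    out_size: int = 128,
) -> np.ndarray:
    """Standardize a 3-D scan into an ``out_size``-cubed intensity volume.

    Pipeline: resample to isotropic ``target_spacing`` mm voxels, min-max
    normalize intensities to [0, 1], crop to the foreground bounding box
    (intensity > 0, the skull-stripped background-zero convention), and
    resize to a cube.  An all-zero volume degenerates to a center crop with
    a warning.
    """
    from scipy import ndimage

    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3 or min(volume.shape) < 2:
        raise ValueError(f"expected a non-degenerate 3-D volume, got shape {volume.shape}")
    if not np.all(np.isfinite(volume)):
        raise ValueError("volume contains non-finite values")

    zoom = [s / target_spacing for s in spacing]
    if any(abs(z - 1.0) > 1e-9 for z in zoom):
        volume = ndimage.zoom(volume, zoom, order=1)

    # scale by the maximum, preserving the background-zero convention of
    # skull-stripped scans (negative intensities are clipped first)
    volume = np.clip(volume, 0.0, None)
    vmax = volume.max()
    if vmax > 0:
        volume = volume / vmax

    fg = np.argwhere(volume > 0)
    if fg.size == 0:
        warnings.warn("all-zero volume; falling back to center crop", stacklevel=2)
        c = [s // 2 for s in volume.shape]
        half = [min(s, out_size) // 2 for s in volume.shape]
        sl = tuple(slice(max(0, c[i] - half[i]), c[i] + half[i]) for i in range(3))
        volume = volume[sl]
    else:
        lo, hi = fg.min(axis=0), fg.max(axis=0) + 1
        volume = volume[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]

    zoom2 = [out_size / s for s in volume.shape]
    out = ndimage.zoom(volume, zoom2, order=1, grid_mode=True, mode="nearest")
    # interpolation may over/undershoot slightly off-grid; re-clip to [0, 1]
    out = np.clip(out, 0.0, 1.0)
    if out.shape != (out_size, out_size, out_size):
        padded = np.zeros((out_size, out_size, out_size))
        sl = tuple(slice(0, min(out.shape[i], out_size)) for i in range(3))
        padded[sl] = out[sl]
        out = padded
    return out


class ImagingAdapter:
    """Four convolutional blocks downsampling a 768x4x4x4 encoder output to a
    flat 256-vector.

    Each block is a 3x3x3 same-padded convolution narrowing the channel count
    (768 -> 512 -> 384 -> 320 -> 256) followed by ReLU; a global average pool
    over the 4x4x4 spatial grid yields the final vector.  Forward-only at
    desk scale: embeddings are normally precomputed upstream.
    """

    CHANNELS = (768, 512, 384, 320, 256)

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.kernels = []
        self.biases = []
        for cin, cout in zip(self.CHANNELS[:-1], self.CHANNELS[1:]):
            fan_in = cin * 27
            self.kernels.append(rng.normal(0, np.sqrt(2.0 / fan_in), (cout, cin, 3, 3, 3)))
            self.biases.append(np.zeros(cout))

    def __call__(self, enc: np.ndarray) -> np.ndarray:
        enc = np.asarray(enc, dtype=float)
        if enc.shape != (768, 4, 4, 4):
            raise ValueError(f"expected encoder output of shape (768, 4, 4, 4), got {enc.shape}")
        x = enc
        for K, b in zip(self.kernels, self.biases):
            x = _conv3d_same(x, K) + b[:, None, None, None]
            x = np.maximum(x, 0.0)
        return x.mean(axis=(1, 2, 3))


def _conv3d_same(x: np.ndarray, K: np.ndarray) -> np.ndarray:
    """(Cin, D, H, W) * (Cout, Cin, 3, 3, 3) -> (Cout, D, H, W), zero pad."""
    cin, D, H, W = x.shape
    cout = K.shape[0]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    # im2col over the 27 kernel offsets
    cols = np.empty((cin * 27, D * H * W))
    i = 0
    for dz in range(3):
        for dy in range(3):
            for dx in range(3):
                patch = xp[:, dz : dz + D, dy : dy + H, dx : dx + W]
                cols[i * cin : (i + 1) * cin] = patch.reshape(cin, -1)
                i += 1
    Kmat = K.transpose(2, 3, 4, 1, 0).reshape(27 * cin, cout)
    out = Kmat.T @ cols
    return out.reshape(cout, D, H, W)


def adapt_imaging_embedding(enc: np.ndarray, adapter: ImagingAdapter | None = None) -> np.ndarray:
    """Downsample a 768x4x4x4 encoder output into a length-256 vector."""
    if adapter is None:
        adapter = ImagingAdapter()
    return adapter(enc)


class StandInEncoder:
    """Tiny deterministic stand-in producing 768x4x4x4 arrays from 128-cubed
    volumes, so the adapter path is exercisable on CPU without a pretrained
    3-D transformer encoder.  Synthetic: average-pools the volume onto a
    4x4x4 grid and expands channels with a fixed random projection."""

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.proj = rng.normal(0, 1.0 / 8.0, (768, 64))

    def __call__(self, volume: np.ndarray) -> np.ndarray:
        volume = np.asarray(volume, dtype=float)
        if volume.shape != (128, 128, 128):
            raise ValueError(f"expected 128-cubed volume, got {volume.shape}")
        # mean-pool to a 16^3 grid, then view it as 4^3 cells of 4^3 voxels
        grid = volume.reshape(16, 8, 16, 8, 16, 8).mean(axis=(1, 3, 5))
        patches = (
            grid.reshape(4, 4, 4, 4, 4, 4)
            .transpose(0, 2, 4, 1, 3, 5)
            .reshape(64, 64)  # (cell, local patch)
        )
        channels = self.proj @ patches.T  # (768, 64 cells)
        return channels.reshape(768, 4, 4, 4)
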