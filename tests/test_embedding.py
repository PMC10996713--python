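"""Embedding contracts: linear/lookup tokens, sub-volume pipeline, adapter."""

import numpy as np
import pytest

from demiform.embedding import (
    EmbeddingParams,
    ImagingAdapter,
    StandInEncoder,
    adapt_imaging_embedding,
    assemble_tokens,
    embed_categorical,
    embed_numerical,
    prepare_subvolume,
)
from demiform.schema import CodingError, FeatureSchema, FeatureSpec, Record
from demiform.simulate import SyntheticConfig, default_schema, generate_cohort


@pytest.fixture()
def schema_and_params():
    schema = FeatureSchema(
        [
            FeatureSpec("a", "numerical"),
            FeatureSpec("b", "numerical"),
            FeatureSpec("c", "categorical", categories=("x", "y", "z")),
        ]
    )
    params = EmbeddingParams(schema, d_model=8, rng=np.random.default_rng(0))
    return schema, params


class TestNumerical:
    def test_zero_maps_to_bias(self, schema_and_params):
        schema, params = schema_and_params
        tok = embed_numerical(0.0, schema["a"], params)
        np.testing.assert_array_equal(tok, params.numerical["a"]["b"].data)

    def test_linearity(self, schema_and_params):
        schema, params = schema_and_params
        spec = schema["a"]
        b = embed_numerical(0.0, spec, params)
        one = embed_numerical(1.3, spec, params) - b
        two = embed_numerical(2.6, spec, params) - b
        np.testing.assert_allclose(two, 2 * one, atol=1e-6)

    def test_distinct_features_give_distinct_tokens(self):
        schema = FeatureSchema(
            [FeatureSpec("a", "numerical"), FeatureSpec("b", "numerical")]
        )
        for seed in range(100):
            params = EmbeddingParams(schema, d_model=4, rng=np.random.default_rng(seed))
            ta = embed_numerical(0.7, schema["a"], params)
            tb = embed_numerical(0.7, schema["b"], params)
            assert not np.allclose(ta, tb)

    def test_non_finite_raises(self, schema_and_params):
        schema, params = schema_and_params
        with pytest.raises(ValueError):
            embed_numerical(float("nan"), schema["a"], params)


class TestCategorical:
    def test_same_code_bitwise_identical(self, schema_and_params):
        schema, params = schema_and_params
        t1 = embed_categorical("y", schema["c"], params)
        t2 = embed_categorical("y", schema["c"], params)
        np.testing.assert_array_equal(t1, t2)

    def test_cardinality_bounds_distinct_outputs(self, schema_and_params):
        schema, params = schema_and_params
        outs = {embed_categorical(c, schema["c"], params).tobytes() for c in ("x", "y", "z")}
        assert len(outs) == 3

    def test_equivalence_with_onehot_matrix_product(self, schema_and_params):
        schema, params = schema_and_params
        table = params.categorical["c"].data
        for i, code in enumerate(schema["c"].categories):
            onehot = np.zeros(len(schema["c"].categories))
            onehot[i] = 1.0
            np.testing.assert_allclose(
                embed_categorical(code, schema["c"], params), onehot @ table, atol=1e-6
            )

    def test_undeclared_code_raises(self, schema_and_params):
        schema, params = schema_and_params
        with pytest.raises(CodingError, match="'q'"):
            embed_categorical("q", schema["c"], params)


class TestAssemble:
    def test_presence_reflects_observed(self, schema_and_params):
        schema, params = schema_and_params
        rec = Record(
            subject_id="s",
            visit_id="v",
            values={"a": 1.0},
            observed={"a": True, "b": False, "c": False},
            y=np.zeros(13),
            label_mask=np.ones(13),
        )
        seq = assemble_tokens(rec, schema, params)
        np.testing.assert_array_equal(seq.presence, [True, False, False])
        assert np.all(seq.tokens[1] == 0)

    def test_token_order_is_schema_order(self, schema_and_params):
        schema, params = schema_and_params
        rec = Record(
            subject_id="s",
            visit_id="v",
            values={"c": "z", "a": 2.0, "b": -1.0},
            observed={"a": True, "b": True, "c": True},
            y=np.zeros(13),
            label_mask=np.ones(13),
        )
        seq = assemble_tokens(rec, schema, params)
        assert seq.feature_names == ["a", "b", "c"]
        np.testing.assert_array_equal(
            seq.tokens[2], embed_categorical("z", schema["c"], params)
        )

    def test_per_feature_parameter_isolation(self, schema_and_params):
        schema, params = schema_and_params
        rec = Record(
            subject_id="s",
            visit_id="v",
            values={"a": 1.0, "b": 2.0, "c": "x"},
            observed={"a": True, "b": True, "c": True},
            y=np.zeros(13),
            label_mask=np.ones(13),
        )
        before = assemble_tokens(rec, schema, params).tokens.copy()
        params.numerical["a"]["w"].data += 10.0  # perturb feature a only
        after = assemble_tokens(rec, schema, params).tokens
        assert not np.allclose(before[0], after[0])
        np.testing.assert_array_equal(before[1:], after[1:])


class TestSubvolume:
    def test_constant_volume_fills_target_shape(self):
        vol = np.ones((160, 160, 160))
        out = prepare_subvolume(vol, spacing=(1.5, 1.5, 1.5))
        assert out.shape == (128, 128, 128)
        np.testing.assert_allclose(out, 1.0)

    def test_random_volume_shape_and_range(self):
        rng = np.random.default_rng(0)
        vol = rng.random((91, 109, 91))
        out = prepare_subvolume(vol, spacing=(2.0, 2.0, 2.0))
        assert out.shape == (128, 128, 128)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_foreground_crop_contains_bright_cube(self):
        vol = np.zeros((100, 100, 100))
        vol[60:80, 10:30, 40:60] = 1.0  # off-center bright cube
        out = prepare_subvolume(vol, spacing=(1.5, 1.5, 1.5))
        # after cropping to the cube's bounding box, the resized output is
        # (almost) entirely bright
        assert out.mean() > 0.9

    def test_all_zero_volume_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="center crop"):
            out = prepare_subvolume(np.zeros((64, 64, 64)), spacing=(1.5, 1.5, 1.5))
        assert out.shape == (128, 128, 128)

    def test_idempotent_up_to_interpolation(self):
        rng = np.random.default_rng(1)
        # smooth strictly positive volume: idempotence is clean
        base = rng.random((40, 40, 40)) + 0.5
        from scipy import ndimage

        vol = ndimage.gaussian_filter(base, 4)
        once = prepare_subvolume(vol, spacing=(1.5, 1.5, 1.5))
        twice = prepare_subvolume(once, spacing=(1.5, 1.5, 1.5))
        assert np.abs(once - twice).mean() < 1e-3


class TestAdapter:
    def test_output_length_is_256(self):
        enc = np.random.default_rng(0).normal(size=(768, 4, 4, 4))
        vec = adapt_imaging_embedding(enc)
        assert vec.shape == (256,)

    def test_zero_input_zero_biases_gives_zero_vector(self):
        vec = adapt_imaging_embedding(np.zeros((768, 4, 4, 4)))
        np.testing.assert_array_equal(vec, np.zeros(256))

    def test_deterministic(self):
        enc = np.random.default_rng(3).normal(size=(768, 4, 4, 4))
        adapter = ImagingAdapter(seed=7)
        np.testing.assert_array_equal(adapter(enc), adapter(enc))

    def test_wrong_shape_raises(self):
        with pytest.raises(ValueError, match="768"):
            adapt_imaging_embedding(np.zeros((768, 8, 8, 8)))

    def test_standin_encoder_feeds_adapter(self):
        vol = prepare_subvolume(np.random.default_rng(2).random((64, 64, 64)) + 0.1)
        enc = StandInEncoder(seed=0)(vol)
        assert enc.shape == (768, 4, 4, 4)
        assert adapt_imaging_embedding(enc).shape == (256,)


def test_load_volume_reads_nifti_with_spacing(tmp_path):
    import nibabel as nib

    from demiform.embedding import load_volume

    rng = np.random.default_rng(0)
    data = rng.random((20, 22, 20))
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    path = tmp_path / "vol.nii"
    nib.save(nib.Nifti1Image(data, affine), path)
    vol, spacing = load_volume(path)
    np.testing.assert_allclose(vol, data, rtol=1e-6)
    assert spacing == (2.0, 2.0, 2.0)
    out = prepare_subvolume(vol, spacing=spacing)
    assert out.shape == (128, 128, 128)
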