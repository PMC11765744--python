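import numpy as np
import pytest
import sympy

import zoocnn as z
from zoocnn.arch import conv, dense, dropout, flatten, maxpool


class TestShapeRules:
    @pytest.mark.parametrize(
        "in_shape, layer, expected",
        [
            ((224, 224, 1), conv(32), (224, 224, 32)),
            ((28, 28, 64), conv(128), (28, 28, 128)),
            ((5, 5, 1), conv(1, kernel=5, padding="valid"), (1, 1, 1)),
        ],
        ids=["same-224", "same-28", "valid-kernel-covers"],
    )
    def test_conv_output_shape(self, in_shape, layer, expected):
        assert z.conv_output_shape(in_shape, layer) == expected

    def test_valid_kernel_too_large_rejected(self):
        with pytest.raises(ValueError):
            z.conv_output_shape((4, 4, 1), conv(1, kernel=5, padding="valid"))

    @pytest.mark.parametrize(
        "in_shape, window, expected",
        [
            ((224, 224, 16), 2, (112, 112, 16)),
            ((113, 113, 32), 2, (56, 56, 32)),
        ],
    )
    def test_pool_output_shape(self, in_shape, window, expected):
        assert z.pool_output_shape(in_shape, window) == expected

    def test_pool_to_empty_map_rejected(self):
        with pytest.raises(ValueError):
            z.pool_output_shape((1, 1, 8), 2)


class TestParameterCounting:
    def test_baseline_reference_table(self):
        """The 4-block baseline reproduces the published per-layer counts
        and every inferred shape."""
        table = z.count_parameters(z.reference_architectures()["CNN_I"])
        params = [r["No. of Parameters"] for r in table.rows]
        assert params == [448, 0, 4640, 0, 18496, 0, 73856, 0, 0, 12845568, 1539]
        assert table.total_parameters == 12_944_547
        outs = [r["Output Shape"] for r in table.rows]
        assert outs == [
            (224, 224, 16), (112, 112, 16),
            (112, 112, 32), (56, 56, 32),
            (56, 56, 64), (28, 28, 64),
            (28, 28, 128), (14, 14, 128),
            (25088,), (512,), (3,),
        ]

    def test_optimized_reference_conv_counts(self):
        table = z.count_parameters(z.reference_architectures()["ZooCNN"])
        conv_params = [
            r["No. of Parameters"]
            for r in table.rows
            if r["Layer Type"] == "Conv2D"
        ]
        assert conv_params == [320, 18496, 73856, 295168, 1180160]

    def test_kernel_totals(self):
        refs = z.reference_architectures()
        assert z.total_conv_filters(refs["CNN_I"]) == 240
        assert z.total_conv_filters(refs["ZooCNN"]) == 992

    def test_single_unit_dense(self):
        arch = z.ArchitectureSpec((16, 16, 1), [flatten(), dense(1), dense(1)])
        rows = z.count_parameters(arch).rows
        assert rows[-1]["No. of Parameters"] == 2

    def test_conv_counts_invariant_to_spatial_size(self):
        """Conv parameters never depend on the input side; dense parameters
        depend on it only through the flatten length."""
        def build(side):
            return z.ArchitectureSpec(
                (side, side, 1),
                [conv(8), maxpool(), flatten(), dense(4), dense(3)],
            )

        t64, t32 = z.count_parameters(build(64)), z.count_parameters(build(32))
        assert t64.rows[0]["No. of Parameters"] == t32.rows[0]["No. of Parameters"]
        d64 = t64.rows[3]["No. of Parameters"]
        d32 = t32.rows[3]["No. of Parameters"]
        assert d64 == (32 * 32 * 8) * 4 + 4
        assert d32 == (16 * 16 * 8) * 4 + 4
        assert d64 != d32

    def test_dense_without_flatten_rejected(self):
        with pytest.raises(ValueError):
            z.ArchitectureSpec((16, 16, 1), [conv(8), dense(4), dense(3)])

    def test_yaml_roundtrip(self, tmp_path):
        arch = z.reference_architectures()["ZooCNN"]
        arch.to_yaml(tmp_path / "arch.yaml")
        back = z.ArchitectureSpec.from_yaml(tmp_path / "arch.yaml")
        assert z.count_parameters(back).total_parameters == \
            z.count_parameters(arch).total_parameters

    def test_csv_export_layout(self, tmp_path):
        table = z.count_parameters(z.reference_architectures()["CNN_I"])
        text = table.to_csv(tmp_path / "t.csv")
        header = text.splitlines()[0]
        assert header == "Layer Type,Input Shape,Output Shape,No. of Parameters"


class TestSoftmax:
    def test_uniform_on_equal_logits(self):
        np.testing.assert_allclose(
            z.softmax_probabilities((0.0, 0.0, 0.0)), [1 / 3] * 3
        )

    def test_large_logits_no_overflow(self):
        p = z.softmax_probabilities((1000.0, 0.0, 0.0))
        np.testing.assert_allclose(p, [1.0, 0.0, 0.0], atol=1e-12)

    def test_matches_arbitrary_precision_evaluation(self):
        logits = (1.0, 2.0, 3.0)
        exact = [
            float(sympy.exp(x) / sum(sympy.exp(sympy.Rational(k)) for k in (1, 2, 3)))
            for x in map(sympy.Rational, (1, 2, 3))
        ]
        np.testing.assert_allclose(z.softmax_probabilities(logits), exact, rtol=1e-12)

    def test_shift_invariance(self):
        p1 = z.softmax_probabilities((0.5, -1.0, 2.0))
        p2 = z.softmax_probabilities((100.5, 99.0, 102.0))
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            z.softmax_probabilities(())


class TestBuildArchitecture:
    def test_structure_follows_config(self):
        cfg = z.HyperConfig(3, (8, 16, 16), 1e-3, 0.25)
        arch = z.build_architecture(cfg, (32, 32, 1), dense_units=16)
        kinds = [l.kind for l in arch.layers]
        assert kinds == [
            "conv", "maxpool", "conv", "maxpool", "conv", "maxpool",
            "flatten", "dense", "dropout", "dense",
        ]
        assert arch.layers[-1].units == 3
        assert arch.layers[-2].rate == 0.25

    def test_pooling_skipped_on_tiny_maps(self):
        """Deep configurations stay valid on small inputs: pooling stops
        once the feature map would vanish."""
        cfg = z.HyperConfig(7, (4,) * 7, 1e-3, 0.25)
        arch = z.build_architecture(cfg, (16, 16, 1), dense_units=4)
        z.count_parameters(arch)  # must not raise
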