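import numpy as np
import pytest
from hypothesis import given, strategies as st

from ctrace.model_core import (
    N_POOLS,
    BiomeParameterSet,
    PoolLayout,
    SoilTexture,
    TransferSystem,
    ValidationError,
    build_allocation_vector,
    build_transfer_matrix,
    build_transfer_system,
    build_turnover_matrix,
    metabolic_fraction,
)


class TestPoolLayout:
    def test_thirteen_pools(self, layout):
        assert len(layout.names) == N_POOLS

    def test_class_counts(self, layout):
        assert len(layout.indices_of("vegetation")) == 4
        assert len(layout.indices_of("litter")) == 5
        assert len(layout.indices_of("soil")) == 4

    def test_vegetation_first(self, layout):
        assert layout.indices_of("vegetation") == [0, 1, 2, 3]

    def test_bad_layout_rejected(self):
        with pytest.raises(ValidationError):
            PoolLayout(names=("a", "b"), class_of={"a": "vegetation", "b": "soil"})


class TestMetabolicFraction:
    def test_hand_arithmetic_ln20(self):
        # 0.85 - 0.018 * 20 = 0.49 by hand
        assert metabolic_fraction(20.0) == pytest.approx(0.49)

    @given(
        ln=st.floats(0.1, 200.0),
        step=st.floats(0.1, 100.0),
    )
    def test_monotone_non_increasing(self, ln, step):
        assert metabolic_fraction(ln + step) <= metabolic_fraction(ln)

    def test_clamped_at_large_ln(self):
        assert metabolic_fraction(1e6) == 0.0

    def test_clamped_to_unit_interval(self):
        assert 0.0 <= metabolic_fraction(0.001) <= 1.0

    def test_nonpositive_ln_rejected(self):
        with pytest.raises(ValidationError):
            metabolic_fraction(0.0)
        with pytest.raises(ValidationError):
            metabolic_fraction(-3.0)


class TestAllocationVector:
    def test_equal_quarters(self, dbf_params, layout):
        p = dbf_params.with_updates(b=(0.25, 0.25, 0.25, 0.25))
        B = build_allocation_vector(p, layout)
        assert np.array_equal(B[:4], [0.25, 0.25, 0.25, 0.25])
        assert np.array_equal(B[4:], np.zeros(9))

    def test_leaf_only_degenerate(self, dbf_params, layout):
        p = dbf_params.with_updates(b=(1.0, 0.0, 0.0, 0.0))
        B = build_allocation_vector(p, layout)
        expected = np.zeros(N_POOLS)
        expected[layout.index("leaf")] = 1.0
        assert np.array_equal(B, expected)

    def test_sums_to_one(self, table, layout):
        for p in table.values():
            assert build_allocation_vector(p, layout).sum() == pytest.approx(1.0)

    def test_forest_wood_fraction_band(self, table, layout):
        for biome in ("ENF", "EBF", "DNF", "DBF", "MF"):
            B = build_allocation_vector(table[biome], layout)
            assert 0.3 <= B[layout.index("woody")] <= 0.5

    def test_bad_sum_rejected(self, dbf_params):
        with pytest.raises(ValidationError, match="sum"):
            dbf_params.with_updates(b=(0.3, 0.3, 0.2, 0.1))


class TestTransferMatrix:
    def test_diagonal_ones_all_biomes(self, table, loam, layout):
        for p in table.values():
            A = build_transfer_matrix(p, loam, layout)
            assert np.array_equal(np.diag(A), np.ones(N_POOLS))

    def test_sign_and_column_sums_exhaustive(self, table, layout):
        textures = [
            SoilTexture.from_clay_silt(c, s)
            for c, s in [(0.05, 0.1), (0.2, 0.35), (0.4, 0.45)]
        ]
        for p in table.values():
            for tex in textures:
                A = build_transfer_matrix(p, tex, layout)
                off = A - np.eye(N_POOLS)
                assert np.all(off <= 1e-12)
                transfer = (-off).sum(axis=0)
                assert np.all(transfer <= 1.0 + 1e-9)

    def test_woody_column_single_target(self, dbf_params, loam, layout):
        A = build_transfer_matrix(dbf_params, loam, layout)
        col = A[:, layout.index("woody")].copy()
        col[layout.index("woody")] = 0.0
        nonzero = np.nonzero(col)[0]
        assert list(nonzero) == [layout.index("coarse_detritus")]
        assert col[layout.index("coarse_detritus")] == pytest.approx(-1.0)

    def test_coarse_root_routes_to_coarse_detritus(self, dbf_params, loam, layout):
        A = build_transfer_matrix(dbf_params, loam, layout)
        assert A[layout.index("coarse_detritus"), layout.index("coarse_root")] == pytest.approx(-1.0)

    def test_leaf_split_follows_metabolic_fraction(self, dbf_params, loam, layout):
        A = build_transfer_matrix(dbf_params, loam, layout)
        fm = metabolic_fraction(dbf_params.LN)
        assert A[layout.index("surface_metabolic"), layout.index("leaf")] == pytest.approx(-fm)
        assert A[layout.index("surface_structural"), layout.index("leaf")] == pytest.approx(-(1 - fm))

    def test_low_ln_limit_maximizes_metabolic_share(self, dbf_params, loam, layout):
        # as the lignin:N ratio vanishes the metabolic share reaches its cap
        p = dbf_params.with_updates(LN=1e-9)
        A = build_transfer_matrix(p, loam, layout)
        assert A[layout.index("surface_metabolic"), layout.index("leaf")] == pytest.approx(-0.85)

    def test_carbon_conservation_per_donor(self, table, loam, layout):
        # transferred + respired == 1 exactly for every donor pool
        for p in table.values():
            sys = build_transfer_system(p, loam, layout)
            off = sys.A - np.eye(N_POOLS)
            transferred = (-off).sum(axis=0)
            respired = sys.respired_fractions()
            assert np.allclose(transferred + respired, 1.0, atol=1e-12)
            assert np.all(respired >= -1e-12)

    def test_vegetation_pools_do_not_respire(self, dbf_system, layout):
        respired = dbf_system.respired_fractions()
        assert np.allclose(respired[:4], 0.0, atol=1e-12)

    def test_deterministic(self, dbf_params, loam, layout):
        A1 = build_transfer_matrix(dbf_params, loam, layout)
        A2 = build_transfer_matrix(dbf_params, loam, layout)
        assert np.array_equal(A1, A2)

    def test_texture_independent_rows(self, dbf_params, layout):
        # only soil routing responds to texture; litterfall routing does not
        t1 = SoilTexture.from_clay_silt(0.05, 0.1)
        t2 = SoilTexture.from_clay_silt(0.4, 0.45)
        A1 = build_transfer_matrix(dbf_params, t1, layout)
        A2 = build_transfer_matrix(dbf_params, t2, layout)
        for donor in ("leaf", "woody", "fine_root", "coarse_root"):
            j = layout.index(donor)
            assert np.array_equal(A1[:, j], A2[:, j])
        assert not np.array_equal(A1, A2)


class TestTurnoverMatrix:
    def test_all_ones_gives_identity(self, dbf_params):
        p = dbf_params.with_updates(c=tuple([1.0] * N_POOLS))
        assert np.array_equal(build_turnover_matrix(p), np.eye(N_POOLS))

    def test_forest_wood_rates_smallest_vegetation(self, table, layout):
        for biome in ("ENF", "EBF", "DNF", "DBF", "MF"):
            c = np.diag(build_turnover_matrix(table[biome]))
            woody, croot = c[layout.index("woody")], c[layout.index("coarse_root")]
            leaf, froot = c[layout.index("leaf")], c[layout.index("fine_root")]
            assert woody < leaf and woody < froot
            assert croot < leaf and croot < froot

    def test_coarse_detritus_slowest_litter(self, table, layout):
        litter = layout.indices_of("litter")
        for p in table.values():
            c = np.diag(build_turnover_matrix(p))
            assert np.argmin(c[litter]) == litter.index(layout.index("coarse_detritus"))

    def test_nonpositive_rate_rejected(self, dbf_params):
        bad = list(dbf_params.c)
        bad[5] = -0.1
        with pytest.raises(ValidationError):
            dbf_params.with_updates(c=tuple(bad))


class TestSoilTexture:
    def test_simplex_violation_rejected(self):
        with pytest.raises(ValidationError):
            SoilTexture(clay=0.5, silt=0.5, sand=0.5, porosity=0.4)

    def test_bad_porosity_rejected(self):
        with pytest.raises(ValidationError):
            SoilTexture(clay=0.2, silt=0.3, sand=0.5, porosity=0.0)

    def test_from_clay_silt(self):
        t = SoilTexture.from_clay_silt(0.2, 0.3)
        assert t.sand == pytest.approx(0.5)


class TestTransferSystemInvariants:
    def test_system_eigenvalues_positive(self, table, loam):
        rng = np.random.default_rng(7)
        for p in table.values():
            sys = build_transfer_system(p, loam)
            diag = np.concatenate([np.ones(4), rng.uniform(0.01, 1.0, 9)])
            M = sys.A @ np.diag(diag) @ sys.C
            assert np.all(np.linalg.eigvals(M).real > 0)

    def test_positive_offdiagonal_rejected(self):
        A = np.eye(2)
        A[0, 1] = 0.3
        with pytest.raises(ValidationError):
            TransferSystem(A=A, C=np.eye(2), B=np.array([1.0, 0.0]))

    def test_overfull_column_rejected(self):
        A = np.eye(2)
        A[1, 0] = -1.4
        with pytest.raises(ValidationError, match="exceed"):
            TransferSystem(A=A, C=np.eye(2), B=np.array([1.0, 0.0]))
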