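"""The L4 scalar/vector/matrix algebra."""

import numpy as np
import pytest

from spotrecon import (
    L4Matrix,
    L4Number,
    L4Vector,
    PixelSpot,
    Relation,
    basis_transform,
    classify_er,
    er,
    indistinguishability_matrix,
    l4_inner_product,
    l4_matrix_inverse,
    l4_matvec_atomic,
    spot_union,
    transpose_l4,
)
from spotrecon.l4 import SeparatedBasesWarning

ALL_CODES = [format(i, "04b") for i in range(16)]


def pixel_atomic_vector(spot: PixelSpot) -> L4Vector:
    """Relations of a figure with every pixel of its grid (atomic basis)."""
    flat = spot.mask.ravel()
    area = spot.area
    entries = [
        L4Number(int(inn), int(area - int(inn) > 0), int(not inn), 1)
        for inn in flat
    ]
    return L4Vector(tuple(entries), "pixels")


class TestL4Number:
    def test_sixteen_distinct_values_roundtrip(self):
        nums = {L4Number.from_code(c) for c in ALL_CODES}
        assert len(nums) == 16
        for c in ALL_CODES:
            x = L4Number.from_code(c)
            assert x.code == c
            assert L4Number.from_int(x.as_int()) == x
            assert int(x.hex, 16) == x.as_int()

    @pytest.mark.parametrize("bad", ["11", "12001", "1x01"])
    def test_rejects_malformed_codes(self, bad):
        with pytest.raises(ValueError):
            L4Number.from_code(bad)

    @pytest.mark.parametrize("code", ALL_CODES)
    def test_transpose_involution(self, code):
        x = L4Number.from_code(code)
        assert transpose_l4(transpose_l4(x)) == x

    @pytest.mark.parametrize(
        "code,expected",
        [("1101", "1011"), ("1011", "1101"), ("1001", "1001"), ("0111", "0111")],
    )
    def test_transpose_swaps_inclusions_fixes_symmetric(self, code, expected):
        assert transpose_l4(L4Number.from_code(code)).code == expected


class TestClassification:
    @pytest.mark.parametrize(
        "code,relation",
        [
            ("1111", Relation.INTERSECTION),
            ("0111", Relation.SEPARATION),
            ("1101", Relation.INCLUSION_MORE),
            ("1011", Relation.INCLUSION_LESS),
            ("1001", Relation.INDISCERNIBILITY),
        ],
    )
    def test_named_relations_roundtrip(self, code, relation):
        label = classify_er(L4Number.from_code(code))
        assert label.relation is relation
        assert label.code == code
        assert relation.value == code  # label -> code -> label closes

    def test_total_over_all_codes_unnamed_carry_raw(self):
        for code in ALL_CODES:
            label = classify_er(L4Number.from_code(code))
            assert label.code == code
        assert classify_er(L4Number.from_code("0000")).relation is Relation.OTHER


class TestInnerProduct:
    def atoms_vector(self, cover: set, n: int = 3) -> L4Vector:
        entries = [
            L4Number(int(i in cover), int(len(cover - {i}) > 0), int(i not in cover), 1)
            for i in range(n)
        ]
        return L4Vector(tuple(entries), "U")

    def test_overlapping_covers_intersect(self):
        # a over {u1,u2}, b over {u2,u3}: all four bit-sums fire
        assert l4_inner_product(
            self.atoms_vector({0, 1}), self.atoms_vector({1, 2})
        ).code == "1111"

    def test_identical_proper_covers_are_indiscernible(self):
        assert l4_inner_product(
            self.atoms_vector({0, 1}), self.atoms_vector({0, 1})
        ).code == "1001"

    def test_empty_cover_never_connects(self):
        assert l4_inner_product(
            self.atoms_vector(set()), self.atoms_vector({0})
        ).c11 == 0

    def test_mismatch_errors(self):
        with pytest.raises(ValueError):
            l4_inner_product(self.atoms_vector({0}), self.atoms_vector({0}, n=4))
        with pytest.raises(ValueError):
            l4_inner_product(
                self.atoms_vector({0}), L4Vector(self.atoms_vector({0}).entries, "V")
            )

    def test_agrees_with_mask_relation_on_pixel_basis(self, rng):
        """The logical bit sums over a pixel-atomic basis must reproduce
        the elementary relation computed directly from the masks."""
        for _ in range(300):
            a = PixelSpot(rng.random((6, 6)) < rng.uniform(0.1, 0.9))
            b = PixelSpot(rng.random((6, 6)) < rng.uniform(0.1, 0.9))
            assert l4_inner_product(
                pixel_atomic_vector(a), pixel_atomic_vector(b)
            ) == er(a, b)


class TestMatrixOps:
    def test_indistinguishability_structure(self):
        assert indistinguishability_matrix(1).entries == (
            (L4Number.from_code("1001"),),
        )
        I2 = indistinguishability_matrix(2)
        assert I2[0, 0].code == "1001" and I2[1, 1].code == "1001"
        assert I2[0, 1].code == "0111" and I2[1, 0].code == "0111"
        with pytest.raises(ValueError):
            indistinguishability_matrix(0)

    def test_identity_transformation(self, rng):
        for _ in range(20):
            v = pixel_atomic_vector(PixelSpot(rng.random((4, 4)) < 0.5))
            I = indistinguishability_matrix(len(v), "pixels")
            assert l4_matvec_atomic(I, v) == v

    def test_matvec_self_row_classifies_indiscernibility(self, rng):
        v = pixel_atomic_vector(PixelSpot(np.eye(3, dtype=bool)))
        M = L4Matrix((v.entries,), "Y", v.basis_id)
        out = l4_matvec_atomic(M, v)
        assert out[0].code == "1001"

    def test_matvec_basis_mismatch(self):
        v = L4Vector((L4Number.from_code("1001"),), "A")
        M = L4Matrix(((L4Number.from_code("1001"),),), "Y", "B")
        with pytest.raises(ValueError):
            l4_matvec_atomic(M, v)

    def test_inverse_is_entrywise_transposed_transpose(self):
        rows = tuple(
            tuple(L4Number.from_int(v) for v in row)
            for row in [[3, 7, 11], [1, 14, 9]]
        )
        M = L4Matrix(rows, "Y", "X")
        inv = l4_matrix_inverse(M)
        assert inv.shape == (3, 2)
        assert (inv.row_basis_id, inv.col_basis_id) == ("X", "Y")
        for i in range(3):
            for j in range(2):
                assert inv[i, j] == transpose_l4(M[j, i])
        assert l4_matrix_inverse(inv).entries == M.entries

    def test_indistinguishability_is_self_inverse(self):
        I = indistinguishability_matrix(4, "U")
        assert l4_matrix_inverse(I).entries == I.entries


class TestSerialization:
    def test_vector_hex_and_json_roundtrip(self):
        v = L4Vector(tuple(L4Number.from_int(i) for i in range(16)), "X")
        assert L4Vector.from_hex(v.hex, "X") == v
        assert L4Vector.from_json(v.to_json()) == v

    def test_matrix_json_roundtrip(self):
        M = indistinguishability_matrix(3, "U")
        assert L4Matrix.from_json(M.to_json()) == M


class TestBasisTransform:
    @pytest.fixture
    def grid_spots(self, rect_factory):
        shape = (10, 10)
        X = [
            rect_factory(shape, 1, 1, 5, 5),
            rect_factory(shape, 3, 3, 8, 8),
            rect_factory(shape, 6, 1, 9, 4),
        ]
        return shape, X

    def test_same_basis_reproduces_classifications(self, grid_spots, rect_factory):
        shape, X = grid_spots
        for a in [
            rect_factory(shape, 2, 2, 7, 7),
            rect_factory(shape, 1, 1, 5, 5),
            rect_factory(shape, 4, 4, 6, 6),
        ]:
            aX = L4Vector(tuple(er(a, x) for x in X), "X")
            aY = basis_transform(aX, X, X)
            for got, x in zip(aY, X):
                assert classify_er(got).relation is classify_er(er(a, x)).relation

    def test_union_singleton_contains_inner_figure(self, grid_spots, rect_factory):
        shape, X = grid_spots
        union = X[0]
        for x in X[1:]:
            union = spot_union(union, x)
        a = rect_factory(shape, 3, 3, 5, 5)
        aX = L4Vector(tuple(er(a, x) for x in X), "X")
        assert basis_transform(aX, X, [union])[0].c11 == 1

    def test_separated_bases_warn(self, grid_spots, rect_factory):
        shape, X = grid_spots
        a = rect_factory(shape, 2, 2, 4, 4)
        aX = L4Vector(tuple(er(a, x) for x in X), "X")
        with pytest.warns(SeparatedBasesWarning):
            basis_transform(aX, X, [rect_factory(shape, 9, 8, 10, 10)])

    def test_cap_is_enforced_by_name(self, grid_spots, rect_factory):
        shape, X = grid_spots
        a = rect_factory(shape, 2, 2, 4, 4)
        aX = L4Vector(tuple(er(a, x) for x in X), "X")
        with pytest.raises(ValueError, match="cap 2"):
            basis_transform(aX, X, X, cap=2)
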