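import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import build_extended_peptide, chain_of_points
from rinmut.features import (
    VDW_RADII,
    FeatureTable,
    assemble_features,
    compute_sasa,
    conservation_from_msa,
    golden_spiral_points,
    load_conservation,
    load_reference_areas,
    relative_exposure,
)
from rinmut.rin import find_contacts, normalize_weights, simplify
from rinmut.structure_io import Atom, NodeIndexMap, Residue, StructureModel
from rinmut.synthetic import FixtureSpec, make_structure


def single_atom_structure(element="C"):
    return StructureModel(
        chain_id="A",
        residues=[
            Residue(1, "ALA", [Atom("CA", element, (0.0, 0.0, 0.0))])
        ],
    )


def mc_sphere_area(center_idx, centers, radii, n_points=100_000, seed=0):
    """Monte-Carlo oracle: accessible area of one expanded sphere."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n_points, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    r = radii[center_idx]
    pts = centers[center_idx] + r * pts
    free = np.ones(n_points, dtype=bool)
    for j, (c, rj) in enumerate(zip(centers, radii)):
        if j == center_idx:
            continue
        free &= np.sum((pts - c) ** 2, axis=1) > rj**2
    return 4.0 * math.pi * r**2 * free.mean()


class TestComputeSasa:
    def test_isolated_atom_closed_form(self):
        area = compute_sasa(single_atom_structure())
        r = VDW_RADII["C"] + 1.4
        assert area[0] == pytest.approx(4.0 * math.pi * r**2, rel=1e-12)

    def test_fully_enclosed_atom(self):
        """An atom caged inside a tight shell of atoms has ~zero area."""
        shell = golden_spiral_points(40) * 2.0
        residues = [Residue(1, "ALA", [Atom("CA", "C", (0.0, 0.0, 0.0))])]
        atoms = [Atom("CB", "C", tuple(p)) for p in shell]
        residues.append(Residue(3, "ALA", atoms))
        s = StructureModel(chain_id="A", residues=residues)
        area = compute_sasa(s)
        assert area[0] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("separation", [2.5, 3.5])
    def test_two_atom_monte_carlo_oracle(self, separation):
        s = chain_of_points([1, 3], [(0, 0, 0), (separation, 0, 0)])
        got = compute_sasa(s)
        centers = np.array([[0, 0, 0], [separation, 0, 0]], dtype=float)
        radii = np.array([VDW_RADII["C"] + 1.4] * 2)
        for i in range(2):
            oracle = mc_sphere_area(i, centers, radii)
            assert got[i] == pytest.approx(oracle, rel=0.02)

    def test_unknown_element_named_in_error(self):
        s = StructureModel(
            chain_id="A",
            residues=[Residue(1, "ALA", [Atom("XX", "Xx", (0.0, 0.0, 0.0))])],
        )
        with pytest.raises(ValueError, match="XX"):
            compute_sasa(s)

    def test_burial_monotonicity(self):
        """Removing any other residue never decreases a residue's area."""
        s = make_structure(FixtureSpec(n_residues=8, fold_style="helix", seed=2))
        base = compute_sasa(s)
        for drop in range(1, 8):
            kept = [r for i, r in enumerate(s.residues) if i != drop]
            sub = StructureModel(chain_id="A", residues=kept)
            sub_area = compute_sasa(sub)
            names = [r.legacy_position for r in kept]
            for area, pos in zip(sub_area, names):
                assert area >= base[pos - 1] - 1e-9


class TestRelativeExposure:
    def test_zero_area_gives_zero(self):
        ratios, flags = relative_exposure(np.array([0.0]), ["ALA"])
        assert ratios[0] == 0.0 and not flags[0]

    def test_gly_x_gly_self_consistency(self):
        """X in an ideal extended Gly-X-Gly sits near its reference maximum."""
        s = build_extended_peptide(["GLY", "ALA", "GLY"])
        areas = compute_sasa(s)
        ratios, _ = relative_exposure(areas, ["GLY", "ALA", "GLY"])
        assert ratios[1] == pytest.approx(1.0, abs=0.15)

    def test_buried_core_low_ratio(self):
        s = make_structure(FixtureSpec(n_residues=100, seed=4))
        areas = compute_sasa(s)
        ratios, _ = relative_exposure(areas, [r.name for r in s.residues])
        assert ratios.min() < 0.2

    def test_missing_reference_raises(self):
        with pytest.raises(ValueError, match="missing"):
            relative_exposure(np.array([10.0]), ["UNK"])

    def test_reference_table_complete(self):
        ref = load_reference_areas()
        assert len(ref) == 20
        assert all(v > 0 for v in ref.values())


class TestConservation:
    def test_invariant_column_scores_one(self):
        msa = ["AAA", "AAA", "AAA"]
        scores, _ = conservation_from_msa(msa)
        assert scores == pytest.approx([1.0, 1.0, 1.0])

    def test_uniform_column_scores_zero(self):
        msa = [a * 2 for a in "ACDEFGHIKLMNPQRSTVWY"]
        scores, _ = conservation_from_msa(msa, focus_row=0)
        assert scores == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_two_state_column_closed_form(self):
        msa = ["A", "A", "C", "C"]
        scores, _ = conservation_from_msa(msa)
        assert scores[0] == pytest.approx(1.0 - math.log(2) / math.log(20))

    def test_gap_columns_excluded_from_focus(self):
        msa = ["A-C", "AGC", "AGC"]
        scores, _ = conservation_from_msa(msa, focus_row=0)
        assert len(scores) == 2  # focus row has two ungapped positions

    def test_all_gap_column_imputed(self):
        msa = ["AC", "-C", "-C"]
        # column 0 has a single residue (focus only): entropy 0 -> score 1
        scores, imputed = conservation_from_msa(msa)
        assert not imputed.any()
        msa2 = [("focus", "AC")]
        scores2, imputed2 = conservation_from_msa(msa2)
        assert scores2 == pytest.approx([1.0, 1.0])

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(0)
        rows = ["".join(rng.choice(list("ACDEF"), 12)) for _ in range(8)]
        base, _ = conservation_from_msa(rows, focus_row=0)
        permuted = [rows[0]] + [rows[i] for i in (3, 1, 7, 2, 6, 4, 5)]
        again, _ = conservation_from_msa(permuted, focus_row=0)
        assert np.allclose(base, again)

    def test_focus_row_out_of_range(self):
        with pytest.raises(ValueError, match="focus"):
            conservation_from_msa(["AC"], focus_row=3)

    def test_bounds(self):
        rng = np.random.default_rng(1)
        rows = ["".join(rng.choice(list("ACDEFGHIK-"), 30)) for _ in range(15)]
        rows[0] = rows[0].replace("-", "A")
        scores, _ = conservation_from_msa(rows, focus_row=0)
        assert np.all(scores >= 0.0) and np.all(scores <= 1.0)


class TestLoadConservation:
    def _map(self, n=3):
        return NodeIndexMap({i + 1: i for i in range(n)})

    def test_full_table_no_imputation(self, tmp_path):
        p = tmp_path / "cons.tsv"
        p.write_text("1\t0.2\n2\t0.9\n3\t0.5\n")
        scores, imputed = load_conservation(p, self._map(), orientation="higher_conserved")
        assert not imputed.any()
        # min-max scaled, higher stays higher
        assert scores[1] == pytest.approx(1.0)

    def test_missing_node_mean_imputed(self, tmp_path):
        p = tmp_path / "cons.tsv"
        p.write_text("1\t0.0\n3\t1.0\n")
        scores, imputed = load_conservation(p, self._map(), orientation="higher_conserved")
        assert imputed[1]
        assert scores[1] == pytest.approx(0.5)

    def test_grade_scale_auto_detected(self, tmp_path):
        p = tmp_path / "cons.tsv"
        p.write_text("1\t9\n2\t1\n3\t5\n")
        scores, _ = load_conservation(p, self._map())
        assert scores[0] == pytest.approx(1.0)  # grade 9 = most conserved
        assert scores[1] == pytest.approx(0.0)
        assert scores[2] == pytest.approx(0.5)

    def test_continuous_scores_flipped(self, tmp_path):
        """Normalized-rate convention: lower = more conserved, so flipped."""
        p = tmp_path / "cons.tsv"
        p.write_text("1\t-1.5\n2\t0.25\n3\t2.0\n")
        scores, _ = load_conservation(p, self._map())
        assert scores[0] == pytest.approx(1.0)
        assert scores[2] == pytest.approx(0.0)


class TestAssembleFeatures:
    def _net(self, n=5):
        s = make_structure(FixtureSpec(n_residues=n, fold_style="helix", seed=0))
        return normalize_weights(simplify(find_contacts(s), n))

    def test_shape_and_column_span(self):
        net = self._net()
        table = assemble_features(
            net, np.linspace(0, 1, 5), np.linspace(1, 0, 5)
        )
        scaled, _ = table.scaled()
        assert scaled.shape == (5, 2)
        assert scaled.min(axis=0) == pytest.approx([0.0, 0.0])
        assert scaled.max(axis=0) == pytest.approx([1.0, 1.0])

    def test_constant_column_maps_to_half(self):
        net = self._net()
        table = assemble_features(net, np.full(5, 0.3), np.linspace(0, 1, 5))
        scaled, _ = table.scaled()
        assert np.all(scaled[:, 0] == 0.5)

    def test_degree_extra(self):
        net = self._net()
        table = assemble_features(
            net, np.linspace(0, 1, 5), np.linspace(0, 1, 5), extras=("degree",)
        )
        assert table.names[-1] == "degree"
        assert np.array_equal(table.raw[:, 2], net.degree().astype(float))

    def test_coverage_mismatch_raises(self):
        net = self._net()
        with pytest.raises(ValueError, match="cover"):
            assemble_features(net, np.zeros(3), np.zeros(5))

    def test_external_stats_reused(self):
        net = self._net()
        table = assemble_features(net, np.linspace(0, 2, 5), np.linspace(0, 1, 5))
        _, stats = table.scaled()
        scaled, _ = table.scaled(stats=stats)
        assert scaled[:, 0] == pytest.approx(np.linspace(0, 1, 5))


def test_planted_labels_separable_by_features(tiny_benchmark):
    """Per-class feature distributions differ: a shallow rule on
    (exposure, conservation) separates classes with AUC > 0.8."""
    from sklearn.metrics import roc_auc_score
    from sklearn.tree import DecisionTreeClassifier

    b = tiny_benchmark
    X = b.features.raw[b.dataset.node_ids][:, :2]
    y = b.dataset.labels
    clf = DecisionTreeClassifier(max_depth=2, random_state=0).fit(X, y)
    auc = roc_auc_score(y, clf.predict_proba(X)[:, 1])
    assert auc > 0.8
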