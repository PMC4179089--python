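"""Template library handling, influence attribution, and pruning."""

import numpy as np
import pytest

from _oracles import ncc_brute
from nccount import (
    SampleImage,
    Template,
    TemplateLibrary,
    count_cells,
    evaluation_reduction,
    influence,
    prune_library,
    template_similarity,
)
from nccount.errors import ConfigurationError


class TestTemplateLibrary:
    def test_rejects_duplicate_ids_mixed_shapes_and_empty(self):
        rng = np.random.default_rng(0)
        a = Template("a", rng.uniform(0, 1, (3, 3)))
        with pytest.raises(ConfigurationError):
            TemplateLibrary(())
        with pytest.raises(ConfigurationError):
            TemplateLibrary((a, Template("a", rng.uniform(0, 1, (3, 3)))))
        with pytest.raises(ConfigurationError):
            TemplateLibrary((a, Template("b", rng.uniform(0, 1, (4, 4)))))

    def test_save_load_round_trip(self, tmp_path, fixture_library):
        fixture_library.save(tmp_path / "lib")
        loaded = TemplateLibrary.load(tmp_path / "lib")
        assert loaded.ids == fixture_library.ids
        for orig, back in zip(fixture_library.templates, loaded.templates):
            # 16-bit storage quantises to 1/256 of an intensity unit
            np.testing.assert_allclose(back.pixels, orig.pixels, atol=1 / 256 + 1e-9)
        assert loaded.manifest[loaded.ids[0]]["kind"] == fixture_library.manifest[fixture_library.ids[0]]["kind"]

    def test_load_requires_manifest(self, tmp_path):
        with pytest.raises(ConfigurationError):
            TemplateLibrary.load(tmp_path)


class TestSimilarity:
    def test_self_similarity_and_negative_affine(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0, 50, (5, 5))
        lib = TemplateLibrary((Template("a", base), Template("neg", -3.0 * base + 7.0)))
        sim = template_similarity(lib)
        assert sim.loc["a", "a"] == pytest.approx(1.0, abs=1e-12)
        assert sim.loc["a", "neg"] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_naive_pairwise_oracle(self):
        rng = np.random.default_rng(2)
        tpls = tuple(Template(f"t{k}", rng.uniform(0, 255, (6, 6))) for k in range(5))
        sim = template_similarity(TemplateLibrary(tpls))
        for a in range(5):
            for b in range(5):
                expected = ncc_brute(tpls[a].pixels, tpls[b].pixels, 0, 0)
                assert sim.iloc[a, b] == pytest.approx(expected, abs=1e-9)


class TestInfluence:
    def test_single_template_has_full_influence(self, sole_detector_setup):
        sample, library, _ = sole_detector_setup
        solo = TemplateLibrary((library.templates[0],))
        report = influence([sample], solo, 0.67)
        assert report.influence_percent("A") == pytest.approx(100.0)

    def test_exact_copy_has_zero_influence(self, sole_detector_setup):
        sample, library, _ = sole_detector_setup
        a = library.templates[0]
        lib = TemplateLibrary((a, Template("A_copy", a.pixels.copy())))
        report = influence([sample], lib, 0.67)
        assert report.attributed["A_copy"] == 0
        assert report.influence_percent("A") == pytest.approx(100.0)

    def test_sole_detectors_split_influence(self, sole_detector_setup):
        sample, library, placements = sole_detector_setup
        report = influence([sample], library, 0.67)
        n_a = sum(1 for _, _, w in placements if w == "a")
        n_b = sum(1 for _, _, w in placements if w == "b")
        assert report.attributed == {"A": n_a, "B": n_b}
        assert report.total_cells == len(placements)

    def test_percentages_sum_to_hundred(self, default_scene, fixture_library):
        report = influence([default_scene.image], fixture_library, 0.67)
        total_pct = sum(report.influence_percent(i) for i in fixture_library.ids)
        assert total_pct == pytest.approx(100.0, abs=1e-6)
        assert sum(report.attributed.values()) == report.total_cells

    def test_later_members_of_identical_groups_score_zero(self, default_scene, fixture_library):
        # Attribution is order-dependent: within a group of pixel-identical
        # templates only the first in library order can score; the rest see
        # every one of their cells already claimed.
        report = influence([default_scene.image], fixture_library, 0.67)
        groups: dict = {}
        for tpl in fixture_library.templates:
            groups.setdefault(tpl.pixels.tobytes(), []).append(tpl.id)
        for members in groups.values():
            for later in members[1:]:
                assert report.attributed[later] == 0

    def test_zero_cells_warns_and_reports_zero(self, caplog):
        rng = np.random.default_rng(3)
        sample = SampleImage(rng.normal(100, 2, (40, 40)))
        lib = TemplateLibrary((Template("t", rng.uniform(0, 255, (7, 7))),))
        report = influence([sample], lib, 0.99)
        assert report.total_cells == 0
        assert report.influence_percent("t") == 0.0


class TestPruning:
    def test_budget_zero_keeps_sole_detectors(self, sole_detector_setup):
        sample, library, _ = sole_detector_setup
        result = prune_library([sample], library, 0.67, 0.0)
        assert result.pruned.ids == ("A", "B")
        assert result.projected_loss_percent == 0.0
        assert result.removal_log.empty

    def test_budget_zero_removes_exact_duplicate(self, sole_detector_setup):
        sample, library, _ = sole_detector_setup
        a, b = library.templates
        lib3 = TemplateLibrary((a, b, Template("A_copy", a.pixels.copy())))
        result = prune_library([sample], lib3, 0.67, 0.0)
        assert result.pruned.ids == ("A", "B")
        assert result.pruned_count == result.original_count

    def test_zero_influence_removal_leaves_count_unchanged(self, default_scene, fixture_library):
        report = influence([default_scene.image], fixture_library, 0.67)
        keep = [i for i in fixture_library.ids if report.attributed[i] > 0]
        before = count_cells(default_scene.image, list(fixture_library.templates), 0.67).count
        after = count_cells(
            default_scene.image, list(fixture_library.subset(keep).templates), 0.67
        ).count
        assert after == before

    def test_fixture_prune_respects_budget_by_recount(self, default_scene, fixture_library):
        budget = 8.5
        result = prune_library([default_scene.image], fixture_library, 0.67, budget)
        # recount from scratch with the pruned library (independent of cache)
        recount = count_cells(default_scene.image, list(result.pruned.templates), 0.67).count
        original = count_cells(default_scene.image, list(fixture_library.templates), 0.67).count
        realized = 100.0 * abs(original - recount) / original
        assert recount == result.pruned_count
        assert realized <= budget
        assert realized == pytest.approx(result.projected_loss_percent, abs=1e-9)
        # at most one survivor per group of pixel-identical templates
        seen = set()
        for tpl in result.pruned.templates:
            key = tpl.pixels.tobytes()
            assert key not in seen
            seen.add(key)

    def test_never_empties_the_library(self, sole_detector_setup):
        sample, library, _ = sole_detector_setup
        result = prune_library([sample], library, 0.67, 100.0)
        assert len(result.pruned) >= 1

    def test_negative_budget_rejected(self, sole_detector_setup):
        sample, library, _ = sole_detector_setup
        with pytest.raises(ConfigurationError):
            prune_library([sample], library, 0.67, -1.0)


class TestEvaluationReduction:
    def test_published_library_shrink(self):
        assert evaluation_reduction(150, 20) == 87

    def test_evaluations_scale_linearly_with_library_size(self, small_scene, fixture_library):
        full = count_cells(small_scene.image, list(fixture_library.templates), 0.67)
        half_lib = list(fixture_library.templates)[:6]
        half = count_cells(small_scene.image, half_lib, 0.67)
        assert full.n_evaluations == 12 * full.surface.evaluated.size
        assert half.n_evaluations == 6 * half.surface.evaluated.size

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ConfigurationError):
            evaluation_reduction(0, 0)
        with pytest.raises(ConfigurationError):
            evaluation_reduction(10, 11)
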