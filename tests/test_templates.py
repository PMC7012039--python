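"""Template extraction, validation, application, and library building."""
from __future__ import annotations

import pytest
from rdkit import Chem

from retrotree import fixtures as fx
from retrotree.reactions import parse_reaction
from retrotree.templates import (
    GroupLibrary,
    RetroTemplate,
    TemplateExtractionError,
    TemplateLibrary,
    apply_template,
    build_library,
    extract_template,
    find_reaction_center,
    hash_smirks,
    library_overlap,
    validate_template,
)

MAPPED_ESTER = (
    "[CH3:1][CH2:2][C:3](=[O:4])[OH:5].[CH3:6][CH2:7][OH:8]"
    ">>[CH3:1][CH2:2][C:3](=[O:4])[O:8][CH2:7][CH3:6]"
)
# single C-N bond formation between two fragments (N-alkylation with Br)
MAPPED_AMINATION = (
    "[CH3:1][CH2:2][NH2:3].[Br:4][CH2:5][CH3:6]"
    ">>[CH3:1][CH2:2][NH:3][CH2:5][CH3:6]"
)


class TestGroupLibrary:
    def test_default_loads_and_validates(self, group_library):
        assert len(group_library) >= 70
        names = [name for name, _ in group_library.entries]
        assert len(set(names)) == len(names)

    def test_rejects_bad_smarts(self):
        with pytest.raises(ValueError):
            GroupLibrary([("broken", "not a smarts (((")])

    def test_rejects_duplicate_names(self):
        with pytest.raises(ValueError):
            GroupLibrary([("a", "C"), ("a", "N")])


class TestReactionCenter:
    def test_esterification_center_is_acyl_carbon_and_ester_oxygen(self):
        center = find_reaction_center(parse_reaction(MAPPED_ESTER))
        assert center == {3, 8}

    def test_bond_formation_center_is_the_two_bonded_atoms(self):
        center = find_reaction_center(parse_reaction(MAPPED_AMINATION))
        assert center == {3, 5}

    def test_identity_reaction_has_no_center(self):
        with pytest.raises(TemplateExtractionError):
            find_reaction_center(parse_reaction("CCO>>CCO"))
        identity = "[CH3:1][CH2:2][OH:3]>>[CH3:1][CH2:2][OH:3]"
        with pytest.raises(TemplateExtractionError):
            find_reaction_center(parse_reaction(identity))

    def test_charge_only_change_counts(self):
        rxn = parse_reaction("[NH2:1][CH3:2]>>[NH3+:1][CH3:2]")
        assert 1 in find_reaction_center(rxn)


class TestExtraction:
    def test_round_trip_regenerates_source_reactants(self):
        rxn = parse_reaction(MAPPED_ESTER)
        tpl = extract_template(rxn, radius=1)
        outcomes = apply_template(tpl, "CCC(=O)OCC")
        assert any(set(o.molecules) == {"CCC(=O)O", "CCO"} for o in outcomes)

    def test_radius_changes_template_hash(self):
        rxn = parse_reaction(MAPPED_ESTER)
        t1 = extract_template(rxn, radius=1)
        t2 = extract_template(rxn, radius=2)
        assert t1.template_hash != t2.template_hash

    def test_extraction_is_canonical_across_sources(self):
        fam = fx.FAMILIES[0]  # esterification
        pairs = fam.block_pairs()
        hashes = set()
        for a, b in pairs[:5]:
            reaction, _ = fx.couple(fam, a, b)
            tpl = extract_template(parse_reaction(reaction), radius=1)
            hashes.add(tpl.template_hash)
        assert len(hashes) == 1

    def test_spectator_reactant_excluded(self):
        with_agent = MAPPED_ESTER.replace(">>", ".C1CCOC1>>")
        tpl = extract_template(parse_reaction(with_agent), radius=1)
        assert "C1CCOC1" not in tpl.smirks
        assert len(tpl.smirks.split(">>")[1].split(".")) == 2

    def test_group_atoms_pulled_in_beyond_radius(self, group_library):
        # acylation of Boc-carbazate: the protected N sits inside the
        # radius-1 shell, so the whole Boc group joins the pattern
        rxn = parse_reaction(
            "[CH3:1][C:2](=[O:3])[OH:4].[NH2:5][NH:6][C:7](=[O:8])[O:9][C:10]([CH3:11])([CH3:12])[CH3:13]"
            ">>[CH3:1][C:2](=[O:3])[NH:5][NH:6][C:7](=[O:8])[O:9][C:10]([CH3:11])([CH3:12])[CH3:13]"
        )
        bare = extract_template(rxn, radius=1)
        augmented = extract_template(rxn, radius=1, groups=group_library)
        assert "boc_carbamate" in augmented.group_atoms_included
        left = augmented.smirks.split(">>")[0]
        # the tert-butyl quaternary carbon is 4+ bonds from the center
        assert left.count("C;H3") >= 3
        assert bare.template_hash != augmented.template_hash

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            extract_template(parse_reaction(MAPPED_ESTER), radius=-1)


@pytest.fixture(scope="module")
def ester_template():
    return extract_template(parse_reaction(MAPPED_ESTER), radius=1)


@pytest.fixture(scope="module")
def two_templates():
    t1 = extract_template(parse_reaction(MAPPED_ESTER), radius=1)
    t2 = extract_template(parse_reaction(MAPPED_AMINATION), radius=1)
    return t1, t2


class TestApplication:
    def test_no_match_returns_empty(self, ester_template):
        assert apply_template(ester_template, "CCCCCC") == []

    def test_symmetric_sites_deduplicate(self, ester_template):
        # ethylene glycol diester: both ester sites give the same precursors
        outcomes = apply_template(ester_template, "CCC(=O)OCCOC(=O)CC")
        keys = {o.inchi_key_tuple() for o in outcomes}
        assert len(outcomes) == len(keys)

    def test_structure_preservation(self, ester_template):
        outcomes = apply_template(ester_template, "CCCCC(=O)OCCc1ccccc1")
        assert outcomes
        joined = ".".join(outcomes[0].molecules)
        assert "c1ccccc1" in joined  # decoration outside the pattern survives

    def test_match_cap_limits_outcomes(self, ester_template):
        outcomes = apply_template(ester_template, "CCC(=O)OCCOC(=O)CC", max_matches=1)
        assert len(outcomes) <= 1


class TestValidation:
    def test_precise_on_unique_site(self):
        rxn = parse_reaction(MAPPED_ESTER)
        tpl = extract_template(rxn, radius=1)
        assert validate_template(tpl, rxn) == "precise"

    def test_selective_on_second_matching_site(self):
        # product carries a second, asymmetric spectator ester matching the
        # pattern, so re-application also yields non-source precursors
        rxn = parse_reaction(
            "[CH3:1][CH2:2][C:3](=[O:4])[OH:5]."
            "[OH:6][CH2:7][CH2:8][O:9][C:10](=[O:11])[CH2:12][CH2:13][CH3:14]"
            ">>[CH3:1][CH2:2][C:3](=[O:4])[O:6][CH2:7][CH2:8][O:9]"
            "[C:10](=[O:11])[CH2:12][CH2:13][CH3:14]"
        )
        tpl = extract_template(rxn, radius=1)
        assert validate_template(tpl, rxn) == "selective"

    def test_unselective_on_corrupted_template(self):
        rxn = parse_reaction(MAPPED_ESTER)
        tpl = extract_template(rxn, radius=1)
        left, right = tpl.smirks.split(">>")
        corrupted = RetroTemplate(
            smirks=f"{left}>>{right.replace('[OH:', '[NH2:', 1).replace('-[OH]', '-[NH2]')}",
            radius=1,
        )
        assert validate_template(corrupted, rxn) == "unselective"

    def test_failed_when_pattern_cannot_match(self):
        rxn = parse_reaction(MAPPED_ESTER)
        tpl = extract_template(rxn, radius=1)
        other = RetroTemplate(smirks="[Pt:1]>>[Pt:1]", radius=1)
        assert validate_template(other, rxn) == "failed"


class TestTemplateHash:
    def test_map_renumbering_invariant(self):
        a = "[C;H2:1]-[O;H0:2]>>[CH2:1].[OH:2]"
        b = "[C;H2:7]-[O;H0:3]>>[CH2:7].[OH:3]"
        assert hash_smirks(a) == hash_smirks(b)

    def test_identical_strings_identical_hashes(self):
        s = "[C;H2:1]-[O;H0:2]>>[CH2:1].[OH:2]"
        assert hash_smirks(s) == hash_smirks(s)

    def test_different_patterns_differ(self):
        assert hash_smirks("[C:1]>>[C:1]O") != hash_smirks("[C:1]>>[C:1]N")


class TestLibrary:
    def test_min_count_filtering(self, two_templates):
        t1, t2 = two_templates
        records = [("r1", t1), ("r2", t1), ("r3", t1), ("r4", t2)]
        lib2 = build_library(records, min_count=2)
        assert lib2.hashes == [t1.template_hash]
        lib1 = build_library(records, min_count=1)
        assert set(lib1.hashes) == {t1.template_hash, t2.template_hash}
        assert lib1.templates[0].count == 3  # sorted by descending count

    def test_empty_library_is_an_error(self, two_templates):
        t1, _ = two_templates
        with pytest.raises(ValueError):
            build_library([("r1", t1)], min_count=5)

    def test_order_invariance(self, two_templates):
        t1, t2 = two_templates
        records = [("a", t1), ("b", t2), ("c", t1)]
        lib = build_library(records, min_count=1)
        lib_perm = build_library(records[::-1], min_count=1)
        assert lib.hashes == lib_perm.hashes
        assert lib.label_index == lib_perm.label_index

    def test_labels_contiguous(self, policy_world):
        lib = policy_world["library"]
        assert sorted(lib.label_index.values()) == list(range(len(lib)))

    def test_save_load_round_trip(self, tmp_path, two_templates):
        t1, t2 = two_templates
        lib = build_library([("a", t1), ("b", t2)], min_count=1)
        path = tmp_path / "lib.tsv"
        lib.save(path)
        loaded = TemplateLibrary.load(path)
        assert loaded.hashes == lib.hashes
        assert [t.smirks for t in loaded.templates] == [t.smirks for t in lib.templates]


class TestOverlap:
    def _lib(self, templates):
        return build_library([(str(i), t) for i, t in enumerate(templates)], 1)

    def test_identical_libraries_fully_intersect(self, policy_world):
        lib = policy_world["library"]
        table = library_overlap({"a": lib, "b": lib})
        region = {row.region: row.percent for row in table.itertuples()}
        assert region["a&b"] == 100.0 and region["a"] == 0.0

    def test_disjoint_libraries(self):
        world = fx.generate_world(
            n_reactions=60, n_families=10, max_depth=1, seed=2, n_targets=0
        )
        from retrotree.reactions import curate_records, deduplicate
        from retrotree.templates import extract_templates

        kept, _ = curate_records(world.reactions)
        extracted, _ = extract_templates(deduplicate(kept), validate=False)
        by_family = {}
        for h, t, rxn in extracted:
            by_family.setdefault(rxn.class_label, t)
        templates = list(by_family.values())
        a = self._lib(templates[:3])
        b = self._lib(templates[3:10])
        table = library_overlap({"a": a, "b": b})
        region = {row.region: row.percent for row in table.itertuples()}
        assert region["a"] == 30.0 and region["b"] == 70.0 and region["a&b"] == 0.0

    def test_percentages_sum_to_100(self, policy_world):
        lib = policy_world["library"]
        half_a = self._lib(lib.templates[: len(lib) // 2 + 2])
        half_b = self._lib(lib.templates[len(lib) // 2 - 2 :])
        table = library_overlap({"a": half_a, "b": half_b, "c": lib})
        assert table["percent"].sum() == pytest.approx(100.0)
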