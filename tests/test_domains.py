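import pytest

from domainflux import (
    DomainAnnotation,
    DomainError,
    DomainNetworkSpec,
    Metabolite as M,
    Reaction as R,
    build_domain_network,
    build_network,
    compare_representations,
    enumerate_efms,
    inhibit,
    producing_modes,
    reactions_of_domain,
    remove_reactions,
)


def ext(mid, **kw):
    return M(mid, external=True, **kw)


class TestDomainSpec:
    def test_pdh_spec_builds_single_mode_network(self, pdh_bundle, pdh_efms):
        assert len(pdh_bundle.network.reactions) == 7
        assert len(pdh_efms) == 1
        assert pdh_efms[0].support_ids == set(pdh_bundle.network.reaction_ids)

    def test_tca_domain_spec_has_33_steps(self, domain_bundle):
        assert len(domain_bundle.network.reactions) == 33
        assert domain_bundle.network.reaction_ids == [f"R{i}" for i in range(1, 34)]

    def test_undeclared_catalyst_rejected(self):
        with pytest.raises(DomainError, match="undeclared domain 'X9'"):
            DomainNetworkSpec(
                name="bad",
                domains=(DomainAnnotation("D1"),),
                species=(ext("A"), ext("B")),
                steps=(R("s1", {"A": -1, "B": 1}, catalysts=("X9",)),),
            )

    def test_duplicate_step_rejected(self):
        with pytest.raises(DomainError, match="duplicate step"):
            DomainNetworkSpec(
                name="bad",
                domains=(),
                species=(ext("A"), ext("B")),
                steps=(
                    R("s1", {"A": -1, "B": 1}),
                    R("s1", {"B": -1, "A": 1}),
                ),
            )

    def test_invalid_role_rejected(self):
        with pytest.raises(DomainError, match="role"):
            DomainAnnotation("D1", role="cofactor")

    def test_enzyme_map_covers_every_step(self, domain_bundle):
        mapped = {s for steps in domain_bundle.spec.enzyme_map.values() for s in steps}
        assert mapped == set(domain_bundle.network.reaction_ids)


class TestReactionsOfDomain:
    def test_nad_fad_binding_domain_touches_the_shared_e3_steps(self, domain_bundle):
        assert reactions_of_domain(domain_bundle.network, "PdhD2") == {"R5", "R6", "R7"}

    def test_regulatory_domain_touches_nothing(self, domain_bundle):
        assert reactions_of_domain(domain_bundle.network, "PdhB2") == set()

    def test_binding_domain_found_through_its_complexes(self, domain_bundle):
        assert reactions_of_domain(domain_bundle.network, "SucC1") == {
            "R15", "R23", "R24",
        }
        assert reactions_of_domain(domain_bundle.network, "mdh1") == {
            "R18", "R28", "R29",
        }

    def test_unknown_label_rejected(self, domain_bundle):
        with pytest.raises(DomainError, match="unknown domain"):
            reactions_of_domain(domain_bundle.network, "NotADomain")


class TestInhibition:
    def test_blocking_the_shared_lipoamide_step_kills_atp_production(
        self, domain_bundle, domain_efms
    ):
        report = inhibit(domain_bundle.network, domain_efms, "R5")
        assert len(report.removed_modes) == 5
        assert len(report.surviving_modes) == 1
        assert "ATP" in report.lost_capabilities

    def test_domain_target_resolves_like_its_reactions(
        self, domain_bundle, domain_efms
    ):
        by_domain = inhibit(domain_bundle.network, domain_efms, "PdhD2")
        by_reactions = inhibit(domain_bundle.network, domain_efms, ["R5", "R6", "R7"])
        assert {m.signed_support for m in by_domain.removed_modes} == {
            m.signed_support for m in by_reactions.removed_modes
        }

    def test_classical_pdh_knockout_leaves_an_atp_producer(
        self, classical_bundle, classical_efms
    ):
        report = inhibit(classical_bundle.network, classical_efms, "pdh")
        assert len(report.removed_modes) == 3
        assert "ATP" not in report.lost_capabilities
        assert any(m.overall.get("ATP", 0) > 0 for m in report.surviving_modes)

    def test_partition_is_exhaustive_for_every_reaction(
        self, classical_bundle, classical_efms
    ):
        all_supports = classical_efms.signed_supports
        for rid in classical_bundle.network.reaction_ids:
            report = inhibit(classical_bundle.network, classical_efms, rid)
            got = {m.signed_support for m in report.removed_modes} | {
                m.signed_support for m in report.surviving_modes
            }
            assert got == all_supports
            assert not (
                {m.signed_support for m in report.removed_modes}
                & {m.signed_support for m in report.surviving_modes}
            )

    def test_filtering_agrees_with_reenumeration_on_fixtures(
        self, domain_bundle, domain_efms
    ):
        net = domain_bundle.network
        for rid in ("R5", "R18", "R22", "R25"):
            report = inhibit(net, domain_efms, rid)
            reduced = enumerate_efms(remove_reactions(net, [rid]))
            assert reduced.signed_supports == {
                m.signed_support for m in report.surviving_modes
            }

    def test_target_absent_from_all_supports_changes_nothing(self):
        # "dead" needs the unproducible internal E, so no mode can use it
        net = build_network(
            [ext("A"), M("B"), ext("C"), ext("D"), M("E")],
            [
                R("r1", {"A": -1, "B": 1}),
                R("r2", {"B": -1, "C": 1}),
                R("dead", {"B": -1, "E": -1, "D": 1}),
            ],
        )
        efms = enumerate_efms(net)
        report = inhibit(net, efms, "dead")
        assert report.removed_modes == ()
        assert len(report.surviving_modes) == len(efms)
        assert report.lost_capabilities == ()

    def test_unresolvable_target_rejected(self, domain_bundle, domain_efms):
        with pytest.raises(DomainError):
            inhibit(domain_bundle.network, domain_efms, "R99")
        with pytest.raises(DomainError, match="resolves to no reaction"):
            inhibit(domain_bundle.network, domain_efms, "PdhB2")


class TestProducingModes:
    def test_two_atp_producers_in_each_representation(
        self, classical_bundle, classical_efms, domain_bundle, domain_efms
    ):
        assert len(producing_modes(classical_efms, "ATP", net=classical_bundle.network)) == 2
        assert len(producing_modes(domain_efms, "ATP", net=domain_bundle.network)) == 2

    def test_chain_sink_is_never_consumed(self, chain_net):
        efms = enumerate_efms(chain_net)
        assert producing_modes(efms, "Cext", "consume", net=chain_net) == []

    def test_internal_or_unknown_metabolite_rejected(
        self, classical_bundle, classical_efms
    ):
        with pytest.raises(DomainError, match="internal"):
            producing_modes(classical_efms, "OAA", net=classical_bundle.network)
        with pytest.raises(DomainError, match="unknown"):
            producing_modes(classical_efms, "XYZ", net=classical_bundle.network)


class TestCompareRepresentations:
    def test_classical_and_domain_tca_are_in_bijection(
        self, classical_efms, domain_efms
    ):
        match = compare_representations(classical_efms, domain_efms)
        assert match.is_bijection
        assert len(match.pairs) == 6

    def test_identity_on_equal_sets(self, classical_efms):
        match = compare_representations(classical_efms, classical_efms)
        assert match.is_bijection

    def test_swapping_arguments_inverts_the_mapping(self, classical_efms, domain_efms):
        fwd = compare_representations(classical_efms, domain_efms)
        rev = compare_representations(domain_efms, classical_efms)
        fwd_pairs = {
            (left.signed_support, rights[0].signed_support)
            for left, rights in fwd.pairs
        }
        rev_pairs = {
            (rights[0].signed_support, left.signed_support)
            for left, rights in rev.pairs
        }
        assert fwd_pairs == rev_pairs

    def test_lumped_enzyme_reaction_matches_domain_resolution(self, pdh_efms):
        lumped = build_network(
            [ext("Pyr"), ext("CoA"), ext("NAD"), ext("AcCoA"), ext("CO2"), ext("NADH")],
            [R("pdh", {"Pyr": -1, "CoA": -1, "NAD": -1,
                       "AcCoA": 1, "CO2": 1, "NADH": 1})],
        )
        match = compare_representations(enumerate_efms(lumped), pdh_efms)
        assert match.is_bijection

    def test_disjoint_networks_report_unmatched(self, chain_net, parallel_net):
        match = compare_representations(
            enumerate_efms(chain_net), enumerate_efms(parallel_net)
        )
        assert not match.pairs
        assert len(match.unmatched_left) == 1
        assert len(match.unmatched_right) == 2

    def test_aliases_reconcile_renamed_externals(self, chain_net):
        renamed = build_network(
            [ext("Source"), M("B"), ext("Sink")],
            [R("R1", {"Source": -1, "B": 1}), R("R2", {"B": -1, "Sink": 1})],
        )
        plain = compare_representations(
            enumerate_efms(chain_net), enumerate_efms(renamed)
        )
        assert not plain.pairs
        aliased = compare_representations(
            enumerate_efms(chain_net),
            enumerate_efms(renamed),
            aliases={"Source": "Aext", "Sink": "Cext"},
        )
        assert aliased.is_bijection
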