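import random

import pytest

from quartpac.fixtures import ChainSpec, FixtureSpec, make_structure
from quartpac.mutations import (
    MutationRecord,
    align_canonical_to_chain,
    deduplicate,
    filter_mutations,
    map_mutations,
    read_mutation_table,
)


def rec(**kw):
    base = dict(uniprot_accession="P12345", gene="G", canonical_position=10,
                wt_aa="A", mut_aa="V", sample_id="S1",
                somatic_status="Confirmed somatic variant",
                screen_type="whole genome",
                mutation_class="Substitution - Missense")
    base.update(kw)
    return MutationRecord(**base)


class TestFilter:
    def test_nonsense_removed_and_good_kept(self):
        records = [rec(mutation_class="Substitution - Nonsense"), rec()]
        assert filter_mutations(records) == [rec()]

    def test_each_criterion_independently(self):
        violations = [
            rec(mutation_class="Substitution - Nonsense"),
            rec(wt_aa="V", mut_aa="V"),
            rec(somatic_status="Variant of unknown origin"),
            rec(somatic_status="germline"),
            rec(screen_type="targeted gene panel"),
            rec(uniprot_accession=""),
        ]
        passing = rec(sample_id="KEEP")
        records = violations + [passing]
        # independent oracle: each predicate applied on its own
        def ok(r):
            return ("missense" in r.mutation_class.lower()
                    and r.wt_aa != r.mut_aa
                    and r.somatic_status.lower() in
                    {"confirmed somatic variant",
                     "reported in another sample as somatic"}
                    and r.screen_type.lower() in {"whole genome", "whole gene"}
                    and bool(r.uniprot_accession))
        expected = [r for r in records if ok(r)]
        got = filter_mutations(records)
        assert got == expected == [passing]

    def test_reported_in_another_sample_accepted(self):
        r = rec(somatic_status="Reported in another sample as somatic",
                screen_type="whole gene")
        assert filter_mutations([r]) == [r]

    def test_idempotent(self):
        records = [rec(sample_id=f"S{i}", canonical_position=i + 1)
                   for i in range(5)] + [rec(uniprot_accession="")]
        once = filter_mutations(records)
        assert filter_mutations(once) == once


class TestDeduplicate:
    def test_same_sample_duplicate_collapsed(self):
        assert len(deduplicate([rec(), rec()])) == 1

    def test_recurrence_across_samples_kept(self):
        assert len(deduplicate([rec(sample_id="S1"),
                                rec(sample_id="S2")])) == 2

    def test_shuffled_input_matches_set_oracle(self):
        records = [rec(sample_id=f"S{i % 3}", canonical_position=(i % 4) + 1,
                       mut_aa="VLI"[i % 3]) for i in range(30)]
        random.Random(0).shuffle(records)
        got = deduplicate(records)
        keys = {(r.sample_id, r.uniprot_accession, r.canonical_position,
                 r.mut_aa) for r in records}
        assert {(r.sample_id, r.uniprot_accession, r.canonical_position,
                 r.mut_aa) for r in got} == keys
        assert len(got) == len(keys)
        assert deduplicate(got) == got  # idempotent


class TestAlignment:
    def test_identical_sequences(self, two_line_structure):
        _, structure, _ = two_line_structure
        chain = structure.chains[0]
        pm = align_canonical_to_chain(chain.sequence, chain.residues, "A")
        assert pm.ok and pm.alignment_identity == 1.0
        for i, r in enumerate(chain.residues, start=1):
            assert pm.mapping[i] == r.global_index

    def test_disordered_n_terminus_offset(self, two_line_structure):
        """Chain missing the first 10 residues: canonical p maps to chain
        residue p-10."""
        _, structure, _ = two_line_structure
        chain = structure.chains[0]
        canonical = "MKTAYIAKQR" + chain.sequence  # 10 extra leading residues
        pm = align_canonical_to_chain(canonical, chain.residues, "A")
        assert pm.ok
        for p in range(11, len(canonical) + 1):
            assert pm.mapping[p] == chain.residues[p - 11].global_index
        assert all(p > 10 for p in pm.mapping)

    def test_unrelated_sequences_rejected(self, two_line_structure, rng):
        _, structure, _ = two_line_structure
        chain = structure.chains[0]
        junk = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=150))
        pm = align_canonical_to_chain(junk, chain.residues, "A")
        assert not pm.ok and pm.mapping == {}


def _hetero_dimer():
    spec = FixtureSpec(chains=[
        ChainSpec(length=20, accession="P1", chain_id="A"),
        ChainSpec(length=20, accession="P2", chain_id="B",
                  offset=(0.0, 6.0, 0.0)),
    ], seed=0)
    return make_structure(spec)[0]


def _homo_dimer():
    spec = FixtureSpec(chains=[
        ChainSpec(length=20, accession="P1", chain_id="A"),
        ChainSpec(length=20, accession="P1", chain_id="B",
                  offset=(0.0, 6.0, 0.0)),
    ], seed=0)
    return make_structure(spec)[0]


def _maps(structure):
    return {c.chain_id: align_canonical_to_chain(c.sequence, c.residues,
                                                 c.chain_id)
            for c in structure.chains}


class TestMapMutations:
    def test_heterodimer_all_on_owning_chain(self):
        st = _hetero_dimer()
        muts = [rec(uniprot_accession="P1", canonical_position=p,
                    wt_aa=st.chains[0].residues[p - 1].amino_acid,
                    sample_id=f"S{p}") for p in (3, 7, 11)]
        mapped = map_mutations(muts, st, _maps(st))
        assert sorted(mapped.positions) == [3, 7, 11]

    @pytest.mark.parametrize("policy,expected", [
        ("round_robin", [7, 7, 27, 27]),
        ("first_chain", [7, 7, 7, 7]),
    ])
    def test_homodimer_assignment_policies(self, policy, expected):
        st = _homo_dimer()
        wt = st.chains[0].residues[6].amino_acid
        muts = [rec(uniprot_accession="P1", canonical_position=7, wt_aa=wt,
                    sample_id=f"S{i}") for i in range(4)]
        mapped = map_mutations(muts, st, _maps(st), policy=policy)
        assert sorted(mapped.positions) == sorted(expected)
        assert mapped.n == 4  # count preserved

    def test_replicate_all_inflates_count(self):
        st = _homo_dimer()
        wt = st.chains[0].residues[6].amino_acid
        muts = [rec(uniprot_accession="P1", canonical_position=7, wt_aa=wt)]
        mapped = map_mutations(muts, st, _maps(st), policy="replicate_all")
        assert sorted(mapped.positions) == [7, 27]

    def test_unresolvable_positions_dropped_and_counted(self):
        st = _hetero_dimer()
        muts = [rec(uniprot_accession="P1", canonical_position=999)]
        mapped = map_mutations(muts, st, _maps(st))
        assert mapped.n == 0 and mapped.dropped == 1
        assert mapped.is_blank

    def test_mapped_never_exceeds_filtered(self):
        st = _hetero_dimer()
        muts = [rec(uniprot_accession="P1", canonical_position=p,
                    sample_id=f"S{p}") for p in (1, 5, 999)]
        mapped = map_mutations(muts, st, _maps(st))
        assert mapped.n <= len(muts)


def test_read_mutation_table_roundtrip(tmp_path):
    text = ("uniprot\tgene\tposition\twt\tmut\tsample\tstatus\tscreen\tclass\n"
            "P1\tG1\t7\tA\tV\tS1\tConfirmed somatic variant\twhole genome\t"
            "Substitution - Missense\n")
    records = read_mutation_table(text)
    assert len(records) == 1
    r = records[0]
    assert (r.uniprot_accession, r.canonical_position, r.mut_aa) == \
        ("P1", 7, "V")
    path = tmp_path / "muts.tsv"
    path.write_text(text)
    assert read_mutation_table(str(path)) == records
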