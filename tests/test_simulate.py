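"""Generator invariants: planted structure, determinism, effect direction."""

import dataclasses

import numpy as np
import pytest

from mirgrn.conservation import wilcoxon_rank_sum
from mirgrn.simulate import (
    SimulationParams,
    generate_catalog,
    generate_counts,
    generate_genes_and_utrs,
    generate_ppi,
    revcomp,
    simulate,
    write_inputs,
)


class TestCatalog:
    def test_family_counts_by_construction(self):
        p = SimulationParams(
            seed=1, groups=(("a", 1), ("b", 1), ("c", 1), ("d", 1), ("e", 1)),
            n_conserved_families=5, n_specific_per_group=1,
        )
        catalog, ledger = generate_catalog(p)
        labels = list(ledger.labels.values())
        assert labels.count("conserved") == 5
        assert sum(1 for l in labels if l.startswith("group_specific")) == 5

    def test_label_partition(self, small_params):
        _, ledger = generate_catalog(small_params)
        for label in ledger.labels.values():
            assert label == "conserved" or label.startswith("group_specific:")

    def test_conserved_in_every_species_specific_in_one_group(self, small_params):
        catalog, ledger = generate_catalog(small_params)
        groups = ledger.groups
        for fam in catalog.families:
            if fam.label == "conserved":
                assert set(fam.species) == set(small_params.all_species)
            else:
                g = fam.label.split(":")[1]
                assert set(fam.species) == set(groups[g])

    def test_members_share_identical_seed(self, small_params):
        p = dataclasses.replace(small_params, subst_rate=0.25)
        catalog, _ = generate_catalog(p)
        seeds = {f.name: f.seed for f in catalog.families}
        for m in catalog.members:
            assert m.mature[1:8] == seeds[m.family]

    def test_zero_substitution_gives_identical_precursors(self, small_params):
        catalog, _ = generate_catalog(small_params)
        ref = {f.name: f.precursor for f in catalog.families}
        for m in catalog.members:
            assert m.precursor == ref[m.family]

    def test_substitution_rate_sets_mean_hamming_distance(self):
        # binomial mean: rate * (L - 7) non-seed positions, always to another base
        p = SimulationParams(
            seed=3, groups=(("g", 1),), n_conserved_families=0,
            n_specific_per_group=250, loci_per_family=4,
            precursor_len=(80, 80), subst_rate=0.1,
        )
        catalog, _ = generate_catalog(p)
        ref = {f.name: f.precursor for f in catalog.families}
        dists = [
            sum(a != b for a, b in zip(m.precursor, ref[m.family]))
            for m in catalog.members
        ]
        assert len(dists) >= 1000
        expected = 0.1 * (80 - 7)
        assert np.mean(dists) == pytest.approx(expected, rel=0.05)

    def test_ages_conserved_old_specific_young(self, small_params):
        _, ledger = generate_catalog(small_params)
        for fam, label in ledger.labels.items():
            age = ledger.family_age[fam]
            if label == "conserved":
                assert 400 <= age <= 690
            else:
                assert age < 400

    def test_zero_species_group_rejected(self):
        with pytest.raises(ValueError, match="zero species"):
            SimulationParams(groups=(("a", 2), ("b", 0))).validate()

    def test_duplicate_group_labels_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            SimulationParams(groups=(("a", 2), ("a", 1))).validate()


class TestCounts:
    def test_no_dropout_means_every_planted_locus_observed(self, small_params):
        catalog, _ = generate_catalog(small_params)
        counts = generate_counts(catalog, small_params)
        for m in catalog.members:
            assert counts.loc[m.locus_id, m.species] > 0

    def test_counts_zero_outside_own_species(self, small_params):
        catalog, _ = generate_catalog(small_params)
        counts = generate_counts(catalog, small_params)
        for m in catalog.members[:20]:
            others = [s for s in counts.columns if s != m.species]
            assert (counts.loc[m.locus_id, others] == 0).all()

    def test_effect_direction_median_conserved_above_specific(self):
        # planted expression ordering holds in every species, across seeds
        for seed in range(20):
            p = SimulationParams(
                seed=seed, groups=(("g1", 2), ("g2", 2)),
                n_conserved_families=10, n_specific_per_group=5,
                subst_rate=0.0, dropout_prob=0.0,
            )
            catalog, ledger = generate_catalog(p)
            counts = generate_counts(catalog, p)
            fam = {m.locus_id: m.family for m in catalog.members}
            for sp in p.all_species:
                col = counts[sp]
                cons = [col[l] for l in col.index if col[l] > 0 and ledger.labels[fam[l]] == "conserved"]
                spec = [col[l] for l in col.index if col[l] > 0 and ledger.labels[fam[l]] != "conserved"]
                if cons and spec:
                    assert np.median(cons) > np.median(spec)

    def test_null_effect_gives_uniform_rank_test_pvalues(self):
        # equal log-means: one-sided p over seeds should look uniform (K-S)
        from scipy.stats import kstest

        pvals = []
        for seed in range(200):
            p = SimulationParams(
                seed=seed, groups=(("g", 1),), n_conserved_families=10,
                n_specific_per_group=10, loci_per_family=1,
                expr_logmean_conserved=7.0, expr_logmean_specific=7.0,
                subst_rate=0.0, dropout_prob=0.0,
            )
            catalog, ledger = generate_catalog(p)
            counts = generate_counts(catalog, p)
            fam = {m.locus_id: m.family for m in catalog.members}
            sp = p.all_species[0]
            x = [counts.loc[m.locus_id, sp] for m in catalog.members
                 if ledger.labels[fam[m.locus_id]] == "conserved"]
            y = [counts.loc[m.locus_id, sp] for m in catalog.members
                 if ledger.labels[fam[m.locus_id]] != "conserved"]
            pvals.append(wilcoxon_rank_sum(x, y, "greater").p_value)
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestGenesAndUTRs:
    def test_every_planted_site_inside_planted_utr(self, small_params):
        catalog, ledger = generate_catalog(small_params)
        generate_genes_and_utrs(catalog, small_params, ledger)
        for sp, genes in ledger.sites.items():
            for gene, sites in genes.items():
                lo, hi = ledger.utr_boundaries[gene]
                for fam, start, end in sites:
                    assert lo <= start < end <= hi

    def test_planted_site_sequence_is_full_complement_with_A1(self, small_params):
        catalog, ledger = generate_catalog(small_params)
        geneset = generate_genes_and_utrs(catalog, small_params, ledger)
        fam = {f.name: f for f in catalog.families}
        sp = small_params.all_species[0]
        checked = 0
        for gene, sites in ledger.sites[sp].items():
            seq, stop = geneset.transcripts[sp][gene]
            downstream = seq[stop + 3:]
            for name, start, end in sites:
                expected = revcomp(fam[name].mature[1:]) + "A"
                assert downstream[start:end] == expected
                checked += 1
        assert checked > 0

    def test_single_polya_signal_per_gene(self, small_params):
        catalog, ledger = generate_catalog(small_params)
        geneset = generate_genes_and_utrs(catalog, small_params, ledger)
        for sp in small_params.all_species[:2]:
            for gene, (seq, stop) in geneset.transcripts[sp].items():
                downstream = seq[stop + 3:]
                _, utr_end = ledger.utr_boundaries[gene]
                assert downstream.find("AAUAAA") == utr_end - 6

    def test_no_seed_complement_when_sites_disabled(self, small_params):
        p = dataclasses.replace(small_params, sites_per_mirna=0, n_genes=20)
        catalog, ledger = generate_catalog(p)
        geneset = generate_genes_and_utrs(catalog, p, ledger)
        cores = {revcomp(f.mature[1:7]) for f in catalog.families}
        for sp in p.all_species[:2]:
            for gene, (seq, stop) in geneset.transcripts[sp].items():
                downstream = seq[stop + 3:]
                assert not any(core in downstream for core in cores)

    def test_decoy_genes_below_expression_threshold(self, small_params):
        catalog, ledger = generate_catalog(small_params)
        geneset = generate_genes_and_utrs(catalog, small_params, ledger)
        decoys = [g for g, r in ledger.gene_roles.items() if r == "low_tpm_decoy"]
        assert decoys
        assert (geneset.tpm.loc[decoys] < 1.0).all().all()
        others = [g for g, r in ledger.gene_roles.items() if r not in ("low_tpm_decoy",)]
        assert (geneset.tpm.loc[others] >= 1.0).all().all()

    def test_signal_offset_too_small_rejected(self, small_params):
        p = dataclasses.replace(small_params, utr_signal_offset_range=(10, 30))
        catalog, ledger = generate_catalog(p)
        with pytest.raises(ValueError, match="site load"):
            generate_genes_and_utrs(catalog, p, ledger)


class TestPPI:
    def test_strata_respect_score_and_kernel_rules(self, small_params):
        catalog, ledger = generate_catalog(small_params)
        generate_genes_and_utrs(catalog, small_params, ledger)
        generate_ppi(small_params, ledger)
        kernel = set(small_params.kernel_genes)
        kernel_adjacent = set()
        for r in ledger.ppi_strata:
            if r["stratum"] == "a":
                assert r["experimental"] > 0 and r["combined"] > r["experimental"]
                assert r["gene_a"] in kernel or r["gene_b"] in kernel
                kernel_adjacent |= {r["gene_a"], r["gene_b"]}
            elif r["stratum"] == "b":
                assert r["experimental"] == 0 or r["combined"] <= r["experimental"]
            else:
                assert r["experimental"] > 0 and r["combined"] > r["experimental"]
                assert r["gene_a"] not in kernel_adjacent
                assert r["gene_b"] not in kernel_adjacent

    def test_planted_grn_mir_edges_follow_labels(self, small_params):
        *_, ledger = simulate(small_params)
        for group, planted in ledger.planted_grn.items():
            for fam, gene in planted["mir_target"]:
                label = ledger.labels[fam]
                assert label in ("conserved", f"group_specific:{group}")


class TestDeterminism:
    def test_identical_seed_gives_byte_identical_outputs(self, small_params, tmp_path):
        write_inputs(small_params, tmp_path / "a")
        write_inputs(small_params, tmp_path / "b")
        files_a = sorted(f.name for f in (tmp_path / "a").iterdir())
        files_b = sorted(f.name for f in (tmp_path / "b").iterdir())
        assert files_a == files_b
        for name in files_a:
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_different_seeds_differ(self, small_params):
        p2 = dataclasses.replace(small_params, seed=small_params.seed + 1)
        c1, _ = generate_catalog(small_params)
        c2, _ = generate_catalog(p2)
        assert [f.precursor for f in c1.families] != [f.precursor for f in c2.families]
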