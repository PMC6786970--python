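"""Synthetic community generator: determinism, planted signals, truth table."""

import dataclasses

import numpy as np
import pytest

from soilvirome.hostlink import (
    classify_shared_region,
    filter_shared_hits,
    find_protospacers,
    find_shared_regions,
    nearest_host_by_tnf,
    tnf_distance,
    tnf_vector,
)
from soilvirome.simulate import (
    SimulationConfig,
    generate_abundance_and_alignments,
    generate_community,
    generate_geochemistry,
    generate_host_genomes,
    generate_protein_clusters,
    generate_viral_contigs,
    group_abundance_predictors,
    write_community,
)
from soilvirome.stats import pls_fit, prediction_r

TINY = SimulationConfig(
    seed=3,
    n_hosts=4,
    n_viruses=10,
    n_samples_per_habitat=2,
    host_genome_len=8_000,
    viral_contig_len_range=(10_000, 11_000),
    reads_per_sample_range=(2_000, 3_000),
    n_refseq_like=4,
    n_public_like=2,
)


class TestConfigValidation:
    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            dataclasses.replace(TINY, n_hosts=0).validate()

    def test_fractions_above_one_rejected(self):
        with pytest.raises(ValueError):
            dataclasses.replace(TINY, frac_crispr_linked=0.8, frac_tnf_linked=0.5).validate()


class TestDeterminism:
    def test_byte_identical_outputs(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_community(generate_community(TINY), d1)
        write_community(generate_community(TINY), d2)
        for f1 in sorted(d1.iterdir()):
            assert f1.read_bytes() == (d2 / f1.name).read_bytes(), f1.name

    def test_different_seeds_differ(self):
        c1 = generate_community(TINY)
        c2 = generate_community(dataclasses.replace(TINY, seed=4))
        assert c1.viral_seqs != c2.viral_seqs


class TestHostGenomes:
    def test_counts_conserved(self):
        cfg = dataclasses.replace(TINY, n_hosts=10)
        hosts = generate_host_genomes(cfg)
        assert len(hosts.genomes) == 10
        assert len(hosts.lineages) == 10
        assert all(len(l.split(";")) == 7 for l in hosts.lineages.values())

    def test_crispr_arrays_embedded_in_genome(self):
        hosts = generate_host_genomes(TINY)
        for array in hosts.crispr_arrays:
            genome = "".join(hosts.genomes[array.source].values())
            assert array.repeat_seq in genome
            for spacer in array.spacers:
                assert spacer in genome

    def test_tnf_separability(self):
        """Between-host TNF distance exceeds the within-genome half-vs-half
        distance: the composition models are distinguishable signatures."""
        hosts = generate_host_genomes(TINY)
        ids = sorted(hosts.genomes)
        seqs = {b: hosts.genomes[b][f"{b}_c1"] for b in ids}
        for b in ids:
            s = seqs[b]
            within = tnf_distance(tnf_vector(s[: len(s) // 2]), tnf_vector(s[len(s) // 2 :]))
            for other in ids:
                if other != b:
                    between = tnf_distance(tnf_vector(s), tnf_vector(seqs[other]))
                    assert between > within


class TestViralContigs:
    def test_no_crispr_plants_when_fraction_zero(self):
        cfg = dataclasses.replace(TINY, frac_crispr_linked=0.0)
        hosts = generate_host_genomes(cfg)
        viral, _, _ = generate_viral_contigs(cfg, hosts)
        for array in hosts.crispr_arrays:
            for spacer in array.spacers:
                for vid, seq in viral.items():
                    assert find_protospacers(spacer, vid, seq) == []

    def test_planted_protospacer_found_with_pam(self, community):
        arrays = {a.source: a for a in community.hosts.crispr_arrays}
        from soilvirome.hostlink import check_pam

        for link in community.truth.planted_links:
            if link["evidence"] != "crispr":
                continue
            seq = community.viral_seqs[link["virus"]]
            array = arrays[link["host"]]
            matches = [
                m for s in array.spacers for m in find_protospacers(s, link["virus"], seq)
            ]
            assert any(m.mismatches == 0 for m in matches)
            if link["pam_present"]:
                assert any(
                    check_pam(m, seq, community.config.pam_motif, len(m.spacer))
                    for m in matches
                )

    def test_planted_provirus_classified(self, community):
        for link in community.truth.planted_links:
            if link["evidence"] != "provirus":
                continue
            hits = filter_shared_hits(
                find_shared_regions(
                    community.viral_seqs[link["virus"]],
                    link["virus"],
                    community.hosts.genomes[link["host"]],
                )
            )
            assert any(classify_shared_region(h) == "provirus_link" for h in hits)

    def test_tnf_linked_virus_nearest_to_its_host(self, community):
        sigs = {
            b: tnf_vector("".join(s for _, s in sorted(contigs.items())))
            for b, contigs in community.hosts.genomes.items()
        }
        links = [l for l in community.truth.planted_links if l["evidence"] == "tnf"]
        correct = sum(
            nearest_host_by_tnf(community.viral_seqs[l["virus"]], sigs) == l["host"]
            for l in links
        )
        assert correct >= 0.8 * len(links)

    def test_every_link_references_existing_host(self, community):
        for link in community.truth.planted_links:
            assert link["host"] in community.hosts.genomes
        viruses = [l["virus"] for l in community.truth.planted_links]
        assert len(viruses) == len(set(viruses))  # one link status per virus


class TestAbundanceAndAlignments:
    def test_zero_abundance_no_records(self):
        hosts = generate_host_genomes(TINY)
        viral, genes, truth = generate_viral_contigs(TINY, hosts)
        aln, totals, _ = generate_abundance_and_alignments(TINY, viral, hosts, genes, truth)
        planted = truth.planted_abundance
        dna = aln[aln.dataset == "dna"]
        counts = dna.groupby(["target_id", "sample_id"]).size()
        for vid in viral:
            for s in planted.columns:
                if planted.loc[vid, s] == 0:
                    assert (vid, s) not in counts.index

    def test_alignment_ids_exist_in_fastas(self, community):
        contig_ids = set(community.viral_seqs)
        for contigs in community.hosts.genomes.values():
            contig_ids |= set(contigs)
        assert set(community.alignments["target_id"]).issubset(contig_ids)

    def test_depth_tracks_read_total(self):
        """Doubling a sample's reads doubles its expected raw depth."""
        cfg = dataclasses.replace(TINY, alignment_identity_noise=0.0, frac_short_alignments=0.0)
        hosts = generate_host_genomes(cfg)
        viral, genes, truth = generate_viral_contigs(cfg, hosts)
        aln, totals, _ = generate_abundance_and_alignments(cfg, viral, hosts, genes, truth)
        dna = aln[aln.dataset == "dna"]
        counts = dna.groupby("sample_id").size()
        ratios = counts / counts.index.map(totals)
        assert np.allclose(ratios, ratios.iloc[0])  # reads scale exactly with totals

    def test_identity_noise_share_fails_filter(self):
        cfg = dataclasses.replace(
            TINY, alignment_identity_noise=0.5, frac_short_alignments=0.0
        )
        hosts = generate_host_genomes(cfg)
        viral, genes, truth = generate_viral_contigs(cfg, hosts)
        aln, _, _ = generate_abundance_and_alignments(cfg, viral, hosts, genes, truth)
        from soilvirome.abundance import filter_alignments

        dna = aln[aln.dataset == "dna"]
        frac = len(filter_alignments(dna)) / len(dna)
        # binomial expectation: half the records drawn below 95% identity
        assert frac == pytest.approx(0.5, abs=0.03)


class TestProteinClusters:
    def test_within_cluster_pairs_score_above_one(self, community):
        from soilvirome.network import build_network

        edges = build_network(community.pc_membership)
        scored = {frozenset((e.genome_a, e.genome_b)) for e in edges}
        by_cluster: dict[str, list[str]] = {}
        for v, c in community.truth.planted_clusters.items():
            by_cluster.setdefault(c, []).append(v)
        import itertools

        for members in by_cluster.values():
            for a, b in itertools.combinations(members, 2):
                assert frozenset((a, b)) in scored

    def test_disjoint_clusters_no_edge(self):
        from soilvirome.network import build_network

        members = {"a": {"p1", "p2"}, "b": {"p3", "p4"}}
        assert build_network(members) == []

    def test_reference_labels_emitted(self, community):
        assert len(community.reference_lineages) == community.config.n_refseq_like
        for lin in community.reference_lineages.values():
            assert lin.startswith("d__Viruses")


class TestGeochemistry:
    def _noise_free(self):
        # needs >=8 hosts so the archaeal metabolism groups are populated
        cfg = dataclasses.replace(TINY, noise_sd=0.0, n_hosts=8)
        hosts = generate_host_genomes(cfg)
        viral, genes, truth = generate_viral_contigs(cfg, hosts)
        _, _, metadata = generate_abundance_and_alignments(cfg, viral, hosts, genes, truth)
        meta = generate_geochemistry(cfg, truth, hosts, metadata)
        return cfg, hosts, truth, meta

    def test_noise_free_response_exact(self):
        cfg, hosts, truth, meta = self._noise_free()
        pred = group_abundance_predictors(truth, hosts)
        z = (pred - pred.mean()) / pred.std().replace(0.0, 1.0)
        coeffs = np.asarray(cfg.geochem_coefficients)
        expected = z.to_numpy() @ coeffs[0]
        assert np.allclose(meta["CH4_porewater"].to_numpy(), expected)

    def test_pls_recovers_noise_free_relation(self):
        cfg, hosts, truth, meta = self._noise_free()
        pred = group_abundance_predictors(truth, hosts)
        usable = pred.loc[:, pred.std() > 0]
        model = pls_fit(usable, meta["CH4_porewater"].to_numpy(), n_components=min(2, usable.shape[1]))
        assert prediction_r(model)[0] >= 0.999

    def test_label_permutation_destroys_association(self, rng):
        cfg, hosts, truth, meta = self._noise_free()
        pred = group_abundance_predictors(truth, hosts)
        usable = pred.loc[:, pred.std() > 0]
        y = meta["CH4_porewater"].to_numpy()
        rs = []
        for _ in range(30):
            perm = rng.permutation(len(y))
            model = pls_fit(usable, y[perm], n_components=1)
            rs.append(prediction_r(model)[0])
        assert abs(np.median(rs)) < 0.5
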