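"""Generator contracts: determinism, truth accounting, planted structure."""

import numpy as np
import pytest

from mirpipe.fold import call_hairpin
from mirpipe.io import ValidationError
from mirpipe.preprocess import classify_read
from mirpipe.synthetic import (
    SimulationConfig,
    expected_proportions,
    generate_reference_bundle,
    simulate_count_table,
    simulate_libraries,
)


class TestBundleGeneration:
    def test_mature_is_substring_of_precursor(self, study):
        _, bundle, planted, _, _ = study
        for m in planted:
            assert m.precursor_seq[m.mature_start : m.mature_end] == m.sequence

    def test_counts_match_config(self, study):
        config, bundle, planted, _, _ = study
        assert len(bundle.specific_precursors) == config.n_known_specific
        assert len(bundle.selected_precursors) == config.n_known_selected
        assert sum(1 for m in planted if m.kind == "novel") == config.n_novel

    def test_planted_loci_recorded_in_genome(self, study):
        _, bundle, planted, _, _ = study
        from mirpipe.io import revcomp

        for m in planted:
            if not m.in_genome:
                continue
            locus = bundle.precursor_loci[m.precursor_name]
            segment = bundle.genome[locus.contig][locus.start : locus.end]
            if locus.strand == "-":
                segment = revcomp(segment)
            assert segment == m.precursor_seq

    def test_both_strands_used(self, study):
        _, bundle, _, _, _ = study
        strands = {locus.strand for locus in bundle.precursor_loci.values()}
        assert strands == {"+", "-"}

    def test_deterministic_byte_identical(self, tmp_path, study_config):
        b1, _ = generate_reference_bundle(study_config)
        b2, _ = generate_reference_bundle(study_config)
        d1, d2 = tmp_path / "one", tmp_path / "two"
        b1.write(d1)
        b2.write(d2)
        for f1 in sorted(d1.iterdir()):
            assert f1.read_bytes() == (d2 / f1.name).read_bytes()

    def test_planted_precursors_fold_as_hairpins(self, study):
        _, _, planted, _, _ = study
        accepted = sum(
            call_hairpin(m.precursor_seq, m.mature_start, m.mature_end).is_hairpin
            for m in planted
        )
        assert accepted == len(planted)

    def test_genome_capacity_guard(self):
        config = SimulationConfig(seed=0, n_novel=300, genome_size=5000, n_contigs=1)
        with pytest.raises(ValidationError):
            generate_reference_bundle(config)

    @pytest.mark.parametrize(
        "field,value",
        [("contaminant_fraction", 1.5), ("library_depth", 0),
         ("substitution_rate", -0.1), ("adapter", "ACG")],
    )
    def test_config_validation(self, field, value):
        config = SimulationConfig(**{field: value})
        with pytest.raises(ValidationError):
            config.validate()


class TestLibrarySimulation:
    def test_deterministic(self, study_config):
        bundle, planted = generate_reference_bundle(study_config)
        libs1, _ = simulate_libraries(bundle, planted, study_config)
        libs2, _ = simulate_libraries(bundle, planted, study_config)
        assert libs1 == libs2

    def test_truth_counts_conserve_depth(self, study):
        config, _, _, libraries, truth = study
        counts = truth.origin_counts()
        for lib in config.library_names:
            assert counts[lib].sum() == config.library_depth
            assert len(truth.read_origins[lib]) == len(libraries[lib])

    def test_no_contaminants_when_fraction_zero(self):
        config = SimulationConfig(seed=3, contaminant_fraction=0.0, library_depth=2000)
        bundle, planted = generate_reference_bundle(config)
        _, truth = simulate_libraries(bundle, planted, config)
        names = {m.name for m in planted}
        for origins in truth.read_origins.values():
            assert set(origins) <= names

    def test_clean_channel_reads_equal_mature(self):
        config = SimulationConfig(
            seed=4, substitution_rate=0.0, isomir_end_sd=0.0,
            contaminant_fraction=0.0, library_depth=1000,
        )
        bundle, planted = generate_reference_bundle(config)
        libraries, truth = simulate_libraries(bundle, planted, config)
        by_name = {m.name: m for m in planted}
        for lib, reads in libraries.items():
            for read, origin in zip(reads, truth.read_origins[lib]):
                fate, insert = classify_read(read, config.adapter)
                assert fate == "retained"
                assert insert == by_name[origin].sequence

    def test_fold_change_recovered_against_sampling_oracle(self):
        """Planted fold changes reappear in the counts at the proportions the
        model implies, within binomial sampling error."""
        config = SimulationConfig(
            seed=5, library_depth=100_000, biological_cv=0.0,
            substitution_rate=0.0, isomir_end_sd=0.0,
        )
        bundle, planted = generate_reference_bundle(config)
        _, truth = simulate_libraries(bundle, planted, config)
        counts = truth.origin_counts()
        props = expected_proportions(config, planted)
        control = [l for l in config.library_names if l.startswith("C")]
        treated = [l for l in config.library_names if l.startswith("T")]
        for m in planted:
            if m.fold_change == 1.0:
                continue
            mean_c = counts.loc[m.name, control].mean()
            mean_t = counts.loc[m.name, treated].mean()
            oracle = props.loc[m.name, "treated"] / props.loc[m.name, "control"]
            observed = mean_t / mean_c
            # binomial sd of the ratio, three libraries per condition
            rel_sd = np.sqrt(
                (1 / (3 * config.library_depth * props.loc[m.name, "treated"]))
                + (1 / (3 * config.library_depth * props.loc[m.name, "control"]))
            )
            assert abs(observed / oracle - 1) < 5 * rel_sd + 0.02

    def test_insert_length_mode_is_21(self, study):
        config, _, _, libraries, _ = study
        lengths = []
        for reads in libraries.values():
            for read in reads[:3000]:
                fate, insert = classify_read(read, config.adapter)
                if fate == "retained":
                    lengths.append(len(insert))
        values, freq = np.unique(lengths, return_counts=True)
        assert values[np.argmax(freq)] == 21
        assert min(values) >= 15 and max(values) <= 32


class TestCountTable:
    def test_shape_and_determinism(self, study):
        config, _, planted, _, _ = study
        t1 = simulate_count_table(config, planted, seed=42)
        t2 = simulate_count_table(config, planted, seed=42)
        assert t1.equals(t2)
        assert list(t1.columns) == config.library_names
        assert len(t1) == len(planted)
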