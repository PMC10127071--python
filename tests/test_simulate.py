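"""Synthetic-study generator: determinism and self-consistency."""

import filecmp
import json

import numpy as np
import pytest

from circtrans.consensus import build_consensus
from circtrans.io import (
    parse_bed_caller,
    parse_ciri2,
    parse_gene_models,
    read_fasta,
)
from circtrans.orf import find_circular_orfs
from circtrans.simulate import (
    plan_study,
    plant_circle_with_orf,
    simulate_study,
    write_fixtures,
)
from circtrans.types import CircSequence

FIXTURE_FILES = [
    "genome.fa", "genes.gtf", "ciri2.tsv", "ce2.bed", "findcirc.bed",
    "proteome.fa", "psms.tsv", "prm.csv", "manifest.json",
]


class TestDeterminism:
    def test_same_seed_gives_byte_identical_fixtures(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        simulate_study(5, n_circles=8, outdir=a)
        simulate_study(5, n_circles=8, outdir=b)
        for name in FIXTURE_FILES:
            assert filecmp.cmp(a / name, b / name, shallow=False), name

    def test_regeneration_from_manifest_is_byte_identical(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        manifest = simulate_study(6, n_circles=6, outdir=a)
        roundtripped = json.loads(json.dumps(manifest))
        write_fixtures(roundtripped, b)
        for name in FIXTURE_FILES:
            assert filecmp.cmp(a / name, b / name, shallow=False), name

    def test_different_seeds_differ(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        simulate_study(1, n_circles=5, outdir=a)
        simulate_study(2, n_circles=5, outdir=b)
        assert not filecmp.cmp(a / "genome.fa", b / "genome.fa",
                               shallow=False)


class TestGenomeAndAnnotation:
    def test_gtf_contains_one_gene_per_circle(self, tmp_path):
        simulate_study(3, n_circles=3, outdir=tmp_path)
        gene_ids = set()
        for line in (tmp_path / "genes.gtf").read_text().splitlines():
            attrs = line.split("\t")[8]
            gene_ids.add(attrs.split('gene_id "')[1].split('"')[0])
        assert len(gene_ids) == 3

    def test_planted_exons_re_extracted_from_fasta_match_manifest(self, study):
        outdir, manifest = study
        genome = read_fasta(outdir / "genome.fa")
        for circ in manifest["circles"]:
            for (s, e), expected in zip(circ["exon_intervals"],
                                        circ["exon_seqs_genomic"]):
                assert genome[circ["chrom"]][s:e] == expected, circ["name"]

    def test_annotation_parses_into_gene_models(self, study):
        outdir, manifest = study
        models = parse_gene_models(outdir / "genes.gtf")
        assert len(models) == len(manifest["circles"])
        assert all(len(m.exons) == 4 for m in models)


class TestCircleDesign:
    def test_rolling_322_yields_161aa_junction_spanning_orf(self, rng):
        seq = plant_circle_with_orf(rng, "rolling", 322, 161)
        (orf,) = find_circular_orfs(
            CircSequence(circ_id="r", sequence=seq), min_aa=1
        )
        assert len(orf.protein) == 161
        assert orf.junction_spanning
        assert orf.passes >= 1
        assert orf.termination == "stop"

    def test_single_pass_orf_stays_within_one_pass(self, rng):
        seq = plant_circle_with_orf(rng, "single_pass", 99, 10)
        (orf,) = find_circular_orfs(
            CircSequence(circ_id="s", sequence=seq), min_aa=1
        )
        assert len(orf.protein) == 10
        assert orf.passes == 0
        assert not orf.junction_spanning

    def test_infinite_circle_never_terminates(self, rng):
        seq = plant_circle_with_orf(rng, "infinite", 100)
        (orf,) = find_circular_orfs(
            CircSequence(circ_id="i", sequence=seq), min_aa=1
        )
        assert orf.termination == "none"

    def test_hundred_random_designs_hit_their_targets(self):
        design_rng = np.random.default_rng(99)
        for _ in range(100):
            kind = ["single_pass", "rolling"][int(design_rng.integers(2))]
            if kind == "single_pass":
                target = int(design_rng.integers(8, 50))
                L = 3 * target + 3 + int(design_rng.integers(0, 30))
            else:
                target = int(design_rng.integers(20, 90))
                L = 2 * target + 1
                while L % 3 == 0:
                    L += 1
            seq = plant_circle_with_orf(design_rng, kind, L, target)
            (orf,) = find_circular_orfs(
                CircSequence(circ_id="x", sequence=seq), min_aa=1
            )
            assert len(orf.protein) == target, (kind, L, target)

    def test_infeasible_target_rejected(self, rng):
        # rolling cap: |protein| <= L - 1 for L mod 3 != 0
        with pytest.raises(ValueError):
            plant_circle_with_orf(rng, "rolling", 100, 150)
        with pytest.raises(ValueError):
            plant_circle_with_orf(rng, "single_pass", 30, 50)
        with pytest.raises(ValueError):
            plant_circle_with_orf(rng, "rolling", 99, 60)  # L % 3 == 0


class TestCallerFiles:
    def test_caller_files_use_native_dialect_coordinates(self, study):
        outdir, manifest = study
        all3 = next(c for c in manifest["circles"]
                    if len(c["callers"]) == 3)
        ciri_lines = (outdir / "ciri2.tsv").read_text().splitlines()[1:]
        row = next(l.split("\t") for l in ciri_lines
                   if l.split("\t")[1] == all3["chrom"]
                   and int(l.split("\t")[2]) == all3["start"] + 1)
        assert int(row[3]) == all3["end"]  # 1-based inclusive end == end
        bed_rows = [l.split("\t") for l in
                    (outdir / "findcirc.bed").read_text().splitlines()]
        assert any(int(r[1]) == all3["start"] and int(r[2]) == all3["end"]
                   for r in bed_rows)

    def test_parsed_callers_normalize_to_identical_keys(self, study):
        outdir, manifest = study
        all3 = next(c for c in manifest["circles"] if len(c["callers"]) == 3)
        key = (all3["chrom"], all3["start"], all3["end"], all3["strand"])
        ciri = {j.key for j in parse_ciri2(outdir / "ciri2.tsv")}
        ce2 = {j.key for j in
               parse_bed_caller(outdir / "ce2.bed", "circexplorer2")}
        fc = {j.key for j in
              parse_bed_caller(outdir / "findcirc.bed", "find_circ")}
        assert key in ciri and key in ce2 and key in fc

    def test_consensus_on_fixture_equals_manifest_ground_truth(self, study):
        outdir, manifest = study
        calls = (
            parse_ciri2(outdir / "ciri2.tsv")
            + parse_bed_caller(outdir / "ce2.bed", "circexplorer2")
            + parse_bed_caller(outdir / "findcirc.bed", "find_circ")
        )
        consensus = build_consensus(calls, min_callers=2)
        got = {
            f"{r.junction.chrom}:{r.junction.start}-{r.junction.end}"
            f"({r.junction.strand})"
            for r in consensus
        }
        assert got == set(manifest["consensus_ids"])

    def test_single_caller_circle_excluded_by_consensus(self, study):
        outdir, manifest = study
        singles = [c["circ_id"] for c in manifest["circles"]
                   if len(c["callers"]) == 1]
        assert singles  # the agreement profile plants some
        assert not set(singles) & set(manifest["consensus_ids"])


def test_manifest_is_json_serializable_and_complete():
    manifest = plan_study(13, n_circles=6)
    text = json.dumps(manifest)
    assert json.loads(text) == json.loads(json.dumps(json.loads(text)))
    for key in ("seed", "circles", "consensus_ids", "translated_ids",
                "psms", "reference_proteins", "prm"):
        assert key in manifest
    assert set(manifest["translated_ids"]) <= set(manifest["consensus_ids"])
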