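import numpy as np
import pandas as pd
import pytest

import psnpipe as pp
from psnpipe import stats
from psnpipe.simdata import (CohortConfig, ProgramSpec, QcContaminantFractions,
                             build_gene_table, default_config, expected_probs,
                             fixture_checksum, simulate_cohort, write_fixture)


def test_same_config_same_seed_identical():
    a, _ = simulate_cohort(default_config(seed=9, n_patients=1,
                                          n_nlung_patients=0,
                                          n_cells_per_sample=100))
    b, _ = simulate_cohort(default_config(seed=9, n_patients=1,
                                          n_nlung_patients=0,
                                          n_cells_per_sample=100))
    assert all(x.equals(y) for x, y in zip(a, b))


def test_counts_nonnegative_integer_and_sparse(small_cohort):
    _, cohort, _ = small_cohort
    for m in cohort:
        assert m.counts.dtype.kind == "i"
        assert m.counts.nnz == 0 or m.counts.data.min() >= 0
    m = cohort[1]
    sparsity = 1 - m.counts.nnz / (m.n_genes * m.n_cells)
    assert sparsity > 0.5


def test_planted_low_genes_exact_count():
    cfg = default_config(
        seed=11, n_patients=1, n_nlung_patients=0, n_cells_per_sample=1000,
        groups_per_patient=("GG",),
        qc_contaminant_fractions=QcContaminantFractions(low_genes=0.1))
    _, truth = simulate_cohort(cfg)
    low = truth.cells[truth.cells["qc_class"] == "low_genes"]
    assert len(low) == 100


def test_qc_classes_consistent_with_counts(qc_fixture):
    """Each planted class genuinely trips exactly its own QC rule."""
    from psnpipe.qc import cell_qc_metrics
    _, cm, truth = qc_fixture
    metrics = cell_qc_metrics(cm).set_index("barcode")
    t = truth.cells.set_index("barcode")
    for bc, row in metrics.iterrows():
        cls = t.at[bc, "qc_class"]
        violations = set()
        if row["n_genes"] < 200:
            violations.add("low_genes")
        if row["n_genes"] > 6000:
            violations.add("high_genes")
        if row["mito_frac"] > 0.15:
            violations.add("high_mito")
        if row["n_umis"] > 60000:
            violations.add("high_umi")
        if cls == "none":
            assert not violations, f"{bc}: clean cell trips {violations}"
        else:
            assert cls in violations, f"{bc}: planted {cls} but trips {violations}"


def test_cnv_segment_mean_count_ratio():
    """Config with a single chr1 fold-2 segment: malignant/normal mean-count
    ratio over segment genes lands in (1.6, 2.4) at >= 500 cells."""
    from psnpipe.simdata import CnvSegmentSpec
    cfg = default_config(seed=13, n_patients=1, n_nlung_patients=0,
                         n_cells_per_sample=600,
                         cnv_spec=(CnvSegmentSpec("1", 0.0, 0.6, 2.0),),
                         program_spec=(), signature_shift_spec=())
    cohort, truth = simulate_cohort(cfg)
    seg_genes = truth.genes.query("cnv_segment == 'segment1'")["gene_id"]
    checked = 0
    for cm in cohort:
        t = truth.cells[truth.cells["sample"] == cm.sample_id]
        mal = t["malignant"].to_numpy()
        epi = (t["cell_type"] == "epithelial").to_numpy()
        if mal.sum() < 30 or epi.sum() < 30:
            continue
        idx = cm.genes["gene_id"].isin(seg_genes).to_numpy()
        X = np.asarray(cm.counts.todense(), dtype=float)
        ratio = X[np.ix_(idx, mal)].mean() / X[np.ix_(idx, epi)].mean()
        assert 1.6 < ratio < 2.4
        checked += 1
    assert checked >= 1


def test_carrier_expected_expression_exceeds_noncarrier():
    """On generator means (no sampling), amplified segments are strictly higher."""
    cfg = default_config(seed=1)
    p_mal = expected_probs(cfg, "malignant", "GG", with_cnv=True)
    p_epi = expected_probs(cfg, "epithelial", "GG")
    from psnpipe.simdata import _Model
    model = _Model(cfg)
    amp = model.gene_fold > 1
    dele = (model.gene_fold < 1) & (model.gene_fold > 0)
    assert np.all(p_mal[amp] > p_epi[amp])
    assert np.all(p_mal[dele] < p_epi[dele])


def test_mito_fraction_by_construction(small_cohort):
    _, cohort, _ = small_cohort
    m = cohort[0]
    mito = m.genes["symbol"].str.startswith("MT-").to_numpy()
    X = np.asarray(m.counts.todense(), dtype=float)
    frac = X[mito].sum(axis=0) / X.sum(axis=0)
    assert abs(np.median(frac) - 0.05) < 0.02
    assert np.all(frac < 0.15)


def test_program_gene_list_validation():
    cfg = default_config(seed=0)
    bad = CohortConfig(
        cell_type_spec=cfg.cell_type_spec,
        program_spec=(ProgramSpec(name="p", genes=tuple(f"NOPE{i}" for i in range(50))),))
    with pytest.raises(ValueError, match="unknown genes"):
        bad.validate(build_gene_table(bad)["gene_id"])
    with pytest.raises(ValueError, match="50 distinct"):
        CohortConfig(program_spec=(ProgramSpec(name="p", genes=("a", "b")),)).validate()


def test_weights_must_sum_to_one():
    cfg = default_config(seed=0)
    spec = list(cfg.cell_type_spec)
    spec[0].group_weights = dict(spec[0].group_weights)
    spec[0].group_weights["GG"] += 0.5
    cfg.cell_type_spec = tuple(spec)
    with pytest.raises(ValueError, match="sum to"):
        cfg.validate()


def test_fixture_roundtrip_and_checksum(tmp_path):
    cfg = default_config(seed=21, n_patients=1, n_nlung_patients=1,
                         n_cells_per_sample=80)
    cohort, truth = simulate_cohort(cfg)
    write_fixture(cohort, truth, tmp_path / "fx1")
    back = pp.read_mtx_triplet(tmp_path / "fx1" / cohort[0].sample_id)
    assert cohort[0].equals(back)
    # regenerating from the recorded config + seed gives identical bytes
    cohort2, truth2 = simulate_cohort(cfg)
    write_fixture(cohort2, truth2, tmp_path / "fx2")
    assert fixture_checksum(tmp_path / "fx1") == fixture_checksum(tmp_path / "fx2")


def test_planted_composition_shift_has_power():
    """Planted myeloid decline (nLung > GG > solid) is detected in > 80% of
    label-level cohort replicates by the composition Wilcoxon test."""
    hits = 0
    n_rep = 200
    for rep in range(n_rep):
        cfg = default_config(seed=10_000 + rep)
        _, truth = simulate_cohort(cfg, counts=False)
        labels = truth.cells.rename(columns={"sample": "sample"})[
            ["sample", "cell_type"]]
        meta = (truth.cells[["sample", "patient", "group"]].drop_duplicates()
                .rename(columns={"sample": "sample_id", "patient": "patient_id",
                                 "group": "clinical_group"}))
        comp = stats.composition_table(labels, meta, ["T", "B", "NK", "myeloid"])
        res = stats.compare_composition_groups(comp, "nLung", "solid")
        row = res[res["cell_type"] == "myeloid"].iloc[0]
        a = comp[comp["clinical_group"] == "nLung"]["myeloid"].mean()
        b = comp[comp["clinical_group"] == "solid"]["myeloid"].mean()
        if row["p"] < 0.05 and a > b:
            hits += 1
    assert hits / n_rep > 0.8
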