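"""Relevance classification contract, keyword baseline, and metrics."""

import random
import sys

import pytest

from lbdkit import (
    AbstractRecord,
    ClassificationMetrics,
    ConfusionMatrix,
    ExternalProcessClassifier,
    RelevanceError,
    RelevancePair,
    classify,
    confusion,
    constant_classifier,
    keyword_baseline,
    make_keyword_classifier,
    metrics,
    metrics_report,
    per_category_accuracy,
    read_labeled_pairs,
)

HYP = "erlotinib treats breast cancer through its effect on EGFR"
ENTITIES = ("breast cancer", "EGFR", "erlotinib")


def _pair(doc_id, text, label=None, prediction=None, category=None):
    return RelevancePair(
        abstract=AbstractRecord(doc_id, "", text),
        hypothesis=HYP,
        label=label,
        prediction=prediction,
        category=category,
    )


# --- classify contract -------------------------------------------------------

def test_classify_empty_list():
    assert classify([], constant_classifier(1)) == []


def test_classify_constant_passthrough_preserves_order():
    pairs = [_pair(f"d{i}", f"text {i}") for i in range(5)]
    out = classify(pairs, constant_classifier(1))
    assert [p.prediction for p in out] == [1] * 5
    assert [p.abstract.doc_id for p in out] == [f"d{i}" for i in range(5)]


def test_classify_rejects_out_of_range_prediction():
    with pytest.raises(RelevanceError, match="d0"):
        classify([_pair("d0", "x")], lambda a, h: 2)


# --- keyword baseline --------------------------------------------------------

@pytest.mark.parametrize(
    "text, expected",
    [
        ("erlotinib response in breast cancer patients", 1),  # drug + disease
        ("EGFR is inhibited by erlotinib", 1),  # gene + drug
        ("erlotinib pharmacokinetics only", 0),  # 1 of 3
        ("nothing relevant here", 0),
        ("breast cancer and the EGFRX fusion", 0),  # EGFR inside longer token
        ("breast cancer with EGFR-dependent growth", 1),  # hyphen boundary
    ],
)
def test_keyword_baseline_two_of_three_rule(text, expected):
    assert keyword_baseline(text, ENTITIES) == expected


def test_keyword_classifier_conforms_to_contract():
    clf = make_keyword_classifier(*ENTITIES)
    out = classify([_pair("d0", "erlotinib inhibits EGFR signalling")], clf)
    assert out[0].prediction == 1


def test_keyword_baseline_honors_boolean_queries():
    assert keyword_baseline(
        "the aryl hydrocarbon receptor and breast cancer",
        ("breast cancer", "aryl hydrocarbon receptor|AHR", "stavudine"),
    ) == 1


# --- external process adapter ------------------------------------------------

def test_external_process_classifier_round_trip():
    cmd = [
        sys.executable, "-c",
        "import sys; abstract = sys.stdin.readline().split('\\t')[0]; "
        "print(1 if 'EGFR' in abstract else 0)",
    ]
    clf = ExternalProcessClassifier(cmd)
    assert clf("EGFR is amplified", HYP) == 1
    assert clf("no gene here", HYP) == 0


def test_external_process_classifier_rejects_garbage_output():
    clf = ExternalProcessClassifier([sys.executable, "-c", "print('maybe')"])
    with pytest.raises(RelevanceError, match="maybe"):
        clf("text", HYP)


# --- confusion and metrics ---------------------------------------------------

def test_confusion_basic_tally():
    pairs = [
        _pair("a", "", label=1, prediction=1),
        _pair("b", "", label=1, prediction=0),
        _pair("c", "", label=0, prediction=0),
        _pair("d", "", label=0, prediction=1),
    ]
    assert confusion(pairs) == ConfusionMatrix(tp=1, fn=1, tn=1, fp=1)


def test_confusion_all_correct_has_no_errors():
    pairs = [_pair("a", "", label=1, prediction=1), _pair("b", "", label=0, prediction=0)]
    cm = confusion(pairs)
    assert (cm.fn, cm.fp) == (0, 0)


def test_confusion_requires_labels_and_predictions():
    with pytest.raises(RelevanceError):
        confusion([_pair("a", "", label=1)])


def test_published_confusion_tally_from_72_pairs():
    # 48 relevant (44 retained), 24 irrelevant (5 discarded).
    pairs = (
        [_pair(f"r{i}", "", label=1, prediction=1) for i in range(44)]
        + [_pair(f"m{i}", "", label=1, prediction=0) for i in range(4)]
        + [_pair(f"t{i}", "", label=0, prediction=0) for i in range(5)]
        + [_pair(f"f{i}", "", label=0, prediction=1) for i in range(19)]
    )
    assert confusion(pairs) == ConfusionMatrix(tp=44, fn=4, tn=5, fp=19)


def test_metrics_perfect_classifier():
    m = metrics(ConfusionMatrix(1, 0, 1, 0))
    assert m == ClassificationMetrics(1.0, 1.0, 1.0, 1.0)


def test_metrics_zero_denominator_reports_zero_with_warning():
    with pytest.warns(UserWarning, match="precision"):
        m = metrics(ConfusionMatrix(tp=0, fn=2, tn=3, fp=0))
    assert m.precision == 0.0


def test_metrics_empty_matrix_rejected():
    with pytest.raises(RelevanceError):
        metrics(ConfusionMatrix(0, 0, 0, 0))


def test_metrics_agree_with_bruteforce_recount():
    rng = random.Random(42)
    for _ in range(100):
        n = rng.randrange(1, 100)
        labels = [rng.randrange(2) for _ in range(n)]
        preds = [rng.randrange(2) for _ in range(n)]
        pairs = [
            _pair(f"d{i}", "", label=l, prediction=p)
            for i, (l, p) in enumerate(zip(labels, preds))
        ]
        cm = confusion(pairs)
        # brute-force recount
        tp = sum(1 for l, p in zip(labels, preds) if l == 1 and p == 1)
        fp = sum(1 for l, p in zip(labels, preds) if l == 0 and p == 1)
        fn = sum(1 for l, p in zip(labels, preds) if l == 1 and p == 0)
        tn = n - tp - fp - fn
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (tp, fp, fn, tn)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = metrics(cm)
        assert m.accuracy == pytest.approx((tp + tn) / n)
        if tp + fp:
            assert m.precision == pytest.approx(tp / (tp + fp))
        if tp + fn:
            assert m.recall == pytest.approx(tp / (tp + fn))


def test_recall_monotone_when_false_negative_corrected():
    before = metrics(ConfusionMatrix(tp=3, fn=2, tn=4, fp=1))
    after = metrics(ConfusionMatrix(tp=4, fn=1, tn=4, fp=1))
    assert after.recall > before.recall


# --- per-category accuracy ---------------------------------------------------

def test_per_category_accuracy_independent_buckets():
    pairs = [
        _pair("a", "", label=1, prediction=0, category="c1"),
        _pair("b", "", label=1, prediction=1, category="c1"),
        _pair("c", "", label=0, prediction=0, category="c2"),
        _pair("d", "", label=1, prediction=1, category="c2"),
    ]
    assert per_category_accuracy(pairs) == {"c1": 0.5, "c2": 1.0}


def test_per_category_requires_categories():
    with pytest.raises(RelevanceError):
        per_category_accuracy([_pair("a", "", label=1, prediction=1)])


def test_category_weighted_mean_equals_overall_accuracy():
    rng = random.Random(7)
    for _ in range(20):
        pairs = [
            _pair(
                f"d{i}", "",
                label=rng.randrange(2), prediction=rng.randrange(2),
                category=rng.choice("xyz"),
            )
            for i in range(rng.randrange(3, 40))
        ]
        per_cat = per_category_accuracy(pairs)
        sizes = {c: sum(1 for p in pairs if p.category == c) for c in per_cat}
        weighted = sum(per_cat[c] * sizes[c] for c in per_cat) / len(pairs)
        overall = sum(1 for p in pairs if p.label == p.prediction) / len(pairs)
        assert weighted == pytest.approx(overall)


# --- I/O ---------------------------------------------------------------------

def test_read_labeled_pairs_tsv(tmp_path, tiny_corpus):
    path = tmp_path / "pairs.tsv"
    path.write_text(
        "doc_id\thypothesis\tlabel\tcategory\n"
        f"pm1\t{HYP}\t1\tddi\n"
        f"pm4\t{HYP}\t0\t\n"
    )
    pairs = read_labeled_pairs(path, {r.doc_id: r for r in tiny_corpus})
    assert [(p.abstract.doc_id, p.label, p.category) for p in pairs] == [
        ("pm1", 1, "ddi"), ("pm4", 0, None)
    ]


def test_read_labeled_pairs_unknown_doc(tmp_path, tiny_corpus):
    path = tmp_path / "pairs.tsv"
    path.write_text("doc_id\thypothesis\tlabel\nnope\th\t1\n")
    with pytest.raises(RelevanceError, match="nope"):
        read_labeled_pairs(path, {r.doc_id: r for r in tiny_corpus})


def test_metrics_report_rounding():
    report = metrics_report(ConfusionMatrix(tp=44, fn=4, tn=5, fp=19))
    assert report["display"] == {
        "accuracy": 0.68, "precision": 0.70, "recall": 0.92, "f1": 0.79,
    }
    assert report["metrics"]["precision"] == pytest.approx(44 / 63)
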