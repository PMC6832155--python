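import numpy as np
import pytest

from syncope_nlp.corpus_io import Corpus, EMRRecord


def make_record(i, *, label=None, age=40, icd="", triage="", history="", discharge=""):
    return EMRRecord(
        record_id=f"r{i}",
        encounter_id=f"e{i}",
        age=age,
        icd9_code=icd,
        triage_text=triage,
        history_text=history,
        discharge_text=discharge,
        label=label,
    )


@pytest.fixture
def tiny_corpus():
    """Six labelled records with known term placement, for brute-force oracles."""
    return Corpus(
        records=[
            make_record(0, label=True, icd="780.2",
                        triage="malore improvviso", history="caduta a terra",
                        discharge="sincope di natura vasovagale"),
            make_record(1, label=True, icd="780.2",
                        triage="capogiro e vertigini", history="perdita di coscienza",
                        discharge="sincope"),
            make_record(2, label=True, icd="786.5",
                        triage="svenimento", history="episodio di presincope",
                        discharge="lipotimia"),
            make_record(3, label=False, icd="789.0",
                        triage="dolore addominale", history="nessun trauma",
                        discharge="colica renale"),
            make_record(4, label=False, icd="786.5",
                        triage="dolore toracico", history="cardiopatia nota",
                        discharge="angina stabile"),
            make_record(5, label=False, icd="724.2",
                        triage="lombalgia", history="dolore cronico",
                        discharge="lombalgia acuta"),
        ],
        provenance="fixture",
    )


@pytest.fixture
def small_synthetic():
    """A small seeded synthetic corpus with ground truth (module-scoped cost is low)."""
    from dataclasses import replace

    from syncope_nlp.synthetic_data import default_paper_config, generate_corpus

    cfg = replace(default_paper_config(seed=97), n_records=1200, prevalence=0.05)
    return generate_corpus(cfg)
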