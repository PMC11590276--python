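"""Generate the synthetic linked cohort and write its delimited tables.

Emits persons, labs, admissions, emergency presentations, prescriptions,
GP billing and pathology collections under results/data/, plus the truth
table and the echoed configuration.
"""

from common import parse_args

from ckdcost.synthetic import generate_cohort, write_tables


def main() -> None:
    config, outdir = parse_args(__doc__)
    persons, labs, events, truth = generate_cohort(config)
    write_tables(outdir / "data", config, persons, labs, events, truth)

    n_ckd = int((truth["true_stage"] != "none").sum())
    print(f"generated {len(persons):,} persons ({n_ckd:,} with a true CKD stage), "
          f"{len(labs):,} lab results, {len(events):,} utilisation events")
    print(f"stage mix: {truth['true_stage'].value_counts().to_dict()}")
    print(f"tables written under {outdir / 'data'}")


if __name__ == "__main__":
    main()
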