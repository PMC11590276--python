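"""Price utilisation events into per-person component cost ledgers.

Writes annual_ledgers.csv in long format (person_id, component,
amount_aud_2023) for every included person, using the generated unit-cost
catalogue (2019 prices inflated to 2023 AUD).
"""

from datetime import date

import pandas as pd
from common import parse_args

from ckdcost.costing import build_ledger
from ckdcost.synthetic import generate_cohort, generate_cost_catalog


def main() -> None:
    config, outdir = parse_args(__doc__)
    persons, labs, events, truth = generate_cohort(config)
    catalog = generate_cost_catalog(config)
    window = (date(config.analysis_year, 1, 1), date(config.analysis_year, 12, 31))

    by_person: dict[str, list] = {}
    for e in events:
        by_person.setdefault(e.person_id, []).append(e)

    rows = []
    for p in persons:
        ledger = build_ledger(p.person_id, window, by_person.get(p.person_id, []), catalog)
        for component, amount in ledger.components.items():
            rows.append({"person_id": p.person_id, "component": component,
                         "amount_aud_2023": amount})
    long = pd.DataFrame(rows)
    long.to_csv(outdir / "annual_ledgers.csv", index=False)

    totals = long.groupby("component")["amount_aud_2023"].sum().sort_values(ascending=False)
    print(f"priced {len(events):,} events for {len(persons):,} persons")
    print("total annual cost by component (2023 AUD):")
    print(totals.round(0).to_string())


if __name__ == "__main__":
    main()
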