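"""Events arithmetic: translate a cohort size into an expected events number.

A uniform without-replacement subsample of n_sub cases from a cohort of
N cases with D deaths carries n_sub*D/N deaths on average (the
hypergeometric mean).  Rounding half-up turns the minimum cohort sizes
of a stage II (222 cases, 77 deaths) and stage III (165 cases, 99
deaths) oesophageal cancer cohort into the events numbers that actually
power the log-rank screen.
"""

from progsat import expected_events

cohorts = {"stage II": (222, 77), "stage III": (165, 99)}
targets = {"90% discovery": {"stage II": 65, "stage III": 45},
           "100% discovery": {"stage II": 95, "stage III": 60}}

for label, sizes in targets.items():
    print(f"{label}:")
    for stage, (n_total, d_total) in cohorts.items():
        n_sub = sizes[stage]
        ev = expected_events(n_sub, n_total, d_total)
        print(f"  {stage}: {n_sub} cases of {n_total} "
              f"({d_total} deaths) -> ~{ev} events")
print("\nthe two stages need different cohort sizes but nearly the same "
      "events number (~35),\nbecause log-rank power is driven by deaths, "
      "not enrolment.")
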