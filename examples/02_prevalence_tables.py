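"""Per-collection symbiont prevalence from the published screening counts.

Reconstructs a host-level table whose marginal counts match the published
survey (22 collections, 702 screened isolates) and prints prevalence for a
few collections.
"""

from symbioclim import datasets
from symbioclim.data_io import summarize_prevalence

hosts = datasets.reconstruct_survey_hosts()
summ = summarize_prevalence(hosts)

print(f"{len(hosts)} isolates across {hosts['location_id'].nunique()} collections\n")
for loc in ("VA-mountain-lake-2000", "GA-cooper-creek", "TX-houston-arboretum"):
    sub = summ[(summ["location_id"] == loc) & (summ["symbiont"] != "any")]
    print(loc)
    for _, r in sub.iterrows():
        print(f"  {r['symbiont']:>12}: {r['count']:>3}/{r['total_screened']:<3} = {r['percent']}%")

any_rows = summ[summ["symbiont"] == "any"]
print(f"\nShare of collections with >=50% infected isolates: "
      f"{(any_rows['percent'] >= 50).mean():.2f}")
print("Prevalence varies widely by site; coinfections mean columns need not sum to 100%.")
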