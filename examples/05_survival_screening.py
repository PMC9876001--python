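"""Kaplan-Meier / log-rank screening of the planted prognostic site.

Tumour samples are split at the site's median beta and the two arms'
survival is compared by the log-rank test; p < .05 flags a prognostic site.
"""

from methccanet import key_site_survival, km_estimate, split_by_site
from methccanet.synthetic import generate_dataset

ds = generate_dataset(seed=1)
cases = ds.clinical.case_ids()
bm = ds.beta.subset_samples(cases)
clin = ds.clinical.subset(cases)

site = ds.truth.prognostic_site
table = key_site_survival([site], bm, clin)
row = table.iloc[0]
print(f"prognostic site {site} (planted hazard ratio {ds.truth.hazard_ratio}):")
print(f"  n_high={row.n_high}, n_low={row.n_low}, "
      f"chi2={row.chi_square:.2f}, p={row.p_value:.2e}, flagged={row.significant}")

labels = split_by_site(bm.values.loc[site].to_numpy())
t = clin.table["time"].to_numpy()
e = clin.table["event"].to_numpy(dtype=int)
for grp in ("high", "low"):
    mask = labels == grp
    fit = km_estimate(t[mask], e[mask], group=grp)
    print(f"  {grp}-methylation arm: S(365d) = {fit.survival_at(365):.2f}")
# The hypermethylated arm dies faster: its one-year survival is visibly
# lower and the log-rank test rejects equality of the two curves.
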