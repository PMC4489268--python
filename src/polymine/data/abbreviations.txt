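# Abbreviations that never end a sentence (case-insensitive,
# matched at a word boundary before the period).
e.g.
i.e.
et al.
al.
fig.
figs.
vs.
cf.
ca.
approx.
dr.
mr.
mrs.
ms.
prof.
st.
no.
nos.
ref.
refs.
vol.
eq.
resp.
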