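# Dutch clinical abbreviations that end in a period but do not end a sentence.
dhr.
mevr.
mw.
dr.
drs.
prof.
pat.
fam.
anamn.
lich.
o.a.
o.m.
bijv.
b.v.
evt.
vgl.
ca.
i.v.m.
t.g.v.
t.p.v.
z.n.
m.n.
e.c.i.
vlgs.
volgens.
wo.
di.
do.
vr.
ma.
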