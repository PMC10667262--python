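hgvs_p	hgvs_c	rsid	class	source
	c.115+1G>A	rs104886460	severe	hoglinger
p.C62W			severe	hoglinger
p.P161S			severe	hoglinger
p.G234W			severe	hoglinger
p.G241R			severe	hoglinger
p.F252I			severe	hoglinger
p.H294Q			severe	hoglinger
p.R398*	c.1192C>T	rs121908309	severe	hoglinger
p.G416S			severe	hoglinger
p.V433L			severe	hoglinger
p.L483P	c.1448T>C	rs421016	severe	hoglinger
p.R502H			severe	hoglinger
p.N409S	c.1226A>G	rs76763715	mild	hoglinger
p.W432R			mild	hoglinger
p.N435T			mild	hoglinger
p.E365K	c.1093G>A	rs2230288	risk	hoglinger
p.T408M	c.1223C>T	rs75548401	risk	hoglinger
p.K13R			vus	hoglinger
p.Y61H			vus	hoglinger
p.R78C			vus	hoglinger
p.A97G			vus	proposed
p.L213P			vus	hoglinger
p.A215D			vus	proposed
p.E427K			vus	hoglinger
p.R434C			vus	proposed
p.H529R			vus	hoglinger
p.R534C			vus	hoglinger
p.A495P			vus	hoglinger
p.T408T	c.1224C>T	rs138498426	vus	hoglinger
p.V499V			synonymous_unclassified	hoglinger
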