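strain_id	site_name	mating_type
QS31	Texas - Houston Arboretum	matA1
QS40	Massachusetts - Mt. Greylock	matA2
QS48	North Carolina - Linville Falls	matA2
QS101	Arkansas - Forest City	matA1
QS30	Texas - Carthage	matA3
QS82	Illinois - Effingham	matA3
QS83	Missouri - St. Louis	unknown
QS38	Virginia - Mt. Lake Biological Station	unknown
QS37	Texas - Linden	unknown
QS34	Indiana - Bloomington	matA2
QS36	Kentucky - Land between the Lakes	unknown
QS39	Tennessee - Indian Gap	unknown
QS8	Virginia - Mt. Lake Biological Station	matA2
QS45	Virginia - Mt. Lake Biological Station	matA3
QS49	Virginia - Mt. Lake Biological Station	matA2
QS35	Virginia - Mt. Lake Biological Station	matA3
QS125	Virginia - Mt. Lake Biological Station	matA3
QS135	Virginia - Mt. Lake Biological Station	matA1
QS14	Virginia - Mt. Lake Biological Station	matA2
QS95	Virginia - Mt. Lake Biological Station	matA2
QS131	Virginia - Mt. Lake Biological Station	unknown
QS150	Virginia - Mt. Lake Biological Station	matA3
QS132	Virginia - Mt. Lake Biological Station	matA1
QS136	Virginia - Mt. Lake Biological Station	matA2
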