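ingredient	class	combo_expansion
tenofovir	ARV_AMBIGUOUS
tenofovir disoproxil	ARV_AMBIGUOUS
tenofovir alafenamide	ARV_AMBIGUOUS
emtricitabine	ARV_AMBIGUOUS
lamivudine	ARV_AMBIGUOUS
zidovudine	ARV_CORE
abacavir	ARV_CORE
didanosine	ARV_CORE
stavudine	ARV_CORE
efavirenz	ARV_CORE
nevirapine	ARV_CORE
rilpivirine	ARV_CORE
etravirine	ARV_CORE
doravirine	ARV_CORE
atazanavir	ARV_CORE
darunavir	ARV_CORE
lopinavir	ARV_CORE
ritonavir	ARV_CORE
saquinavir	ARV_CORE
fosamprenavir	ARV_CORE
tipranavir	ARV_CORE
indinavir	ARV_CORE
nelfinavir	ARV_CORE
raltegravir	ARV_CORE
dolutegravir	ARV_CORE
elvitegravir	ARV_CORE
bictegravir	ARV_CORE
cabotegravir	ARV_CORE
maraviroc	ARV_CORE
enfuvirtide	ARV_CORE
ibalizumab	ARV_CORE
fostemsavir	ARV_CORE
truvada		tenofovir disoproxil;emtricitabine
descovy		tenofovir alafenamide;emtricitabine
atripla		efavirenz;tenofovir disoproxil;emtricitabine
biktarvy		bictegravir;tenofovir alafenamide;emtricitabine
genvoya		elvitegravir;tenofovir alafenamide;emtricitabine
stribild		elvitegravir;tenofovir disoproxil;emtricitabine
complera		rilpivirine;tenofovir disoproxil;emtricitabine
odefsey		rilpivirine;tenofovir alafenamide;emtricitabine
symtuza		darunavir;tenofovir alafenamide;emtricitabine
delstrigo		doravirine;lamivudine;tenofovir disoproxil
triumeq		dolutegravir;abacavir;lamivudine
dovato		dolutegravir;lamivudine
juluca		dolutegravir;rilpivirine
combivir		zidovudine;lamivudine
trizivir		abacavir;zidovudine;lamivudine
epzicom		abacavir;lamivudine
kaletra		lopinavir;ritonavir
cimduo		lamivudine;tenofovir disoproxil
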