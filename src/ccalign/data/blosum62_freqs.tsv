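# BLOSUM62 target (joint) substitution frequencies, half-bit score scale.
# Derived from the published 4-decimal BLOSUM62 target-frequency table,
# minimally refined (max change 4.6e-5, i.e. within the 4-dp rounding
# precision of that table) so that round(2*log2(q_ab/(p_a*p_b)))
# reproduces the canonical BLOSUM62 integer scores for all 210 pairs.
# Background frequencies are the marginals of the joint table.
# Lower triangle, row-major; alphabet order:
# alphabet	A	R	N	D	C	Q	E	G	H	I	L	K	M	F	P	S	T	W	Y	V
A	0.02152963133973789
R	0.002305632757673909	0.017826802806616103
N	0.0019041835168493047	0.002005306779236195	0.014120129578986755
D	0.002199638985356951	0.0015998515846629743	0.0037016562314826197	0.02131963120168027
C	0.0016042538549742552	0.0004036861765595613	0.00040275769734737386	0.00039782321606860485	0.01191818732000589
Q	0.0019037368272436972	0.0025055111928208324	0.0015032811096113523	0.0015984758508529831	0.0003021804296804222	0.007310383882195451
E	0.0030019200233450676	0.002702522892341113	0.0022009438587865574	0.004939696077067018	0.0003961905314221238	0.003502188609868766	0.016115341825555223
G	0.005809480487680692	0.001705135020894614	0.002905772846484966	0.002500311321622282	0.0007649378019767062	0.0014033698945192144	0.0019007715395552354	0.03785141704183782
H	0.0011025644675162977	0.0012036885145224527	0.001403020633037488	0.0009975639779846843	0.00020192017307695939	0.0010020526301254026	0.0013993245855496662	0.0010027214869970699	0.009314782063174308
I	0.0032059125681659943	0.0012043032745421556	0.0010031138820861332	0.0011984391528198255	0.0011037046486935425	0.000902537959481894	0.0011996786861249078	0.0014038537597629173	0.0006020159398160178	0.01842580037109129
L	0.004407372847392447	0.0024057642795953767	0.0014035329030127718	0.0014987279530065938	0.0016042541773597363	0.0016033459433501987	0.002000617798148741	0.0021046625350542394	0.0010024346164782473	0.01141658609136919	0.037149938380115106
K	0.003305940722289719	0.0062107090749381096	0.002404833733529036	0.002399900401208721	0.0005028222406635516	0.003105298814819026	0.004103352883341699	0.0025051842291010165	0.0012026954690714448	0.0016038304498299104	0.0025048994069484134	0.01612260244065492
M	0.0013028263124592264	0.0008031686818811859	0.0005018506230754118	0.0004969157445725925	0.00040218065581647434	0.000719727451021424	0.0006984152314187052	0.0007023286473119534	0.0003863480102608481	0.002504490078747317	0.004907511872009445	0.0009023065363422384	0.004005829570418909
F	0.0016037279039367391	0.0009038125983081963	0.0008027518664130785	0.0007978165416214076	0.0005028222318281285	0.0005019140323753685	0.0008991855886377196	0.0012034913370138386	0.0008021735832247337	0.0030056524400209677	0.0054086742479720895	0.0009028172569592673	0.001202696170009109	0.018325466201240113
P	0.0022027316262375864	0.0010021637591953588	0.0009011046340903021	0.0012470455406099865	0.00040007937837373	0.0008005276447817009	0.0013980596050958778	0.0014019744259599605	0.0005000065019385554	0.0010012734075129366	0.0014016902710125266	0.001601951071511097	0.00040994290052302757	0.0005005191748155161	0.019122953472945698
S	0.006309845481615909	0.002305632707407472	0.003105745175649526	0.0028004195202937787	0.00100347331637526	0.0019037364083041605	0.003001919634781332	0.0038068781410544286	0.0011025645932650563	0.0017039598930252671	0.0024047697356445207	0.003105680227524311	0.0009023053323008636	0.0012032071206334182	0.0017020809317042215	0.012618047267952782
T	0.0037064617961441535	0.001804982574572294	0.0022045743048529957	0.0018992483460929662	0.0009033431993150181	0.001403086100818021	0.0020006190568594364	0.002204793681896823	0.0007020443762209176	0.0027052617996063877	0.003305941236217756	0.002304638615054966	0.0010024361422683683	0.0012032078948755623	0.0014016908471549863	0.004707762993914751	0.012517915067756671
W	0.0003885794935137733	0.00028111878692311187	0.00017143934507318024	0.00018345066692086355	0.0001362485044757801	0.000187966568979625	0.0002848205542652593	0.0004093981369095986	0.00018780806290558978	0.0003699540293393659	0.0006889717682111789	0.0002884501004619622	0.00019471677993037	0.0007891011702426048	0.00010706213647131819	0.00028845089625744407	0.00028845202855338884	0.0065091741111537645
Y	0.0013029802743211205	0.0009034532040140047	0.0007022645230434537	0.0005971988222754855	0.00033639292041495316	0.0007018172170142212	0.0008988289405914574	0.0008026132202894671	0.0015027279016433552	0.0014032121355004024	0.0022041516766802163	0.001002586802972773	0.0006015577920653924	0.004206755040562011	0.0005001620282838881	0.0010025903955328487	0.0009024599426699231	0.0008888746146506893	0.010214207775596503
V	0.0051089555735162615	0.001574280373515052	0.0012039462601174103	0.0012991390110143354	0.0014046648161587312	0.0012034968637282166	0.0017008989224241856	0.001804941189730585	0.0006025850885421527	0.012018038651818563	0.009514681608036542	0.0019047874953395472	0.002304799321962921	0.0026057007063898345	0.0012021017606831548	0.002405440999497368	0.0036070032329768493	0.0003892521284600823	0.0015039114567600186	0.01962850080174565
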