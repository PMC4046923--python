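>synthetic_block_00
KMDDSNSKNDGLRGQVSLVNQEAKGLSL
KEDKSSHKLGDLQGEVEQANNELGQLQS
RASDSASKEDDIEHEVEGVKEEAGDLEQ
KMDDFAEILEKIEGKRSGANNEAAALSA
KLKNSATALDDIQSESSKVNKKASNLNT
KMKDSASKLNDIEGEVSNVNNDALGLQR
KLDDSNSKVDDLTSQVSSLNNELAPLSL
KVDSRARKLSDERAEVELSDNEAANLEL
=gabcdefgabcdefgabcdefgabcdef
>synthetic_block_01
KKLIGNLQNKQHDLSEKENSVAEELRGA
LGEIGLEQKKQSKVQQTLGQMAAELKHS
LDEIQQLKSKLRDVSSELGNVKDKADDS
LDEINDLQSKLNRVEKKIGEVANEADAS
LAEIGNLQSRVALEKDTETLVELEADKS
KDEIGLLDKQQDRLSDDRRAVRDEAEDL
QKEIPLIQEKQNRVSDTETEVADELRSA
LDRIETLQSKQTKVKSNENSVAEEAKRV
=efgabcdefgabcdefgabcdefgabcd
>synthetic_block_02
DNKVAQEETDQEDKQTQISLNESLSREL
ALKVHKNETDQTGLEEQVNRLKSASNQL
NNKVAQEETEQRNKEDTALQMQSRSNEL
ENAVTREETRQRGIENLVRRMKGAANSL
DNTVEQEENEVEGLENEVGTRQSELNAL
DVKVKQEEQRQNTKEDDITRLQSASRTS
RNKVNDEETRQEGKENDVTRIQTRSAEA
DNKVDQMRLRLRSIKERVGEMQDQVNLL
=efgabcdefgabcdefgabcdefgabcd
>synthetic_block_03
LSGQEREMANLALARSGIIDKAHSLRHQ
LTELDDDLRRSAQERDKIKDKARTLRQR
LADVDDEKTTLKQTNSGIDTKARNLEPD
LAPQADRFTNLATQRVKQKLLAESLRGD
LDSQKDEFNKLQDTRSKMQREADEIRLK
LDQQQKLFQELANTRTKIRNKARSLTGR
LDPQQVKKDQLDQTRSKIEDKQRDMKNK
LDGQQDEFSKEAQTASSIKNKAQSNKED
=abcdefgabcdefgabcdefgabcdefg
>synthetic_block_04
AQESLPKNEDAAQKAREALVALSQLVQR
AQLRLKPNLNELQNAIEALDALEDLVSR
ADSKLEPNESAVQTVLEALDSLEALFGR
KQESLVPNENAVQEAEPKLNDLEELVSR
AAESLVQNEDKAHNAIDALESLEEDVSR
VQESLSKNEKAVANANEALDNQNSLVES
AQESLVPNRNAVQNATEALDRLEEQVSR
ASSSLRANENAVKNMITQVDSLEDQVSR
=defgabcdefgabcdefgabcdefgabc
>synthetic_block_05
VDRMTVKATSNKGDITQIQSKLKEIETT
VGELKALITSNEGLIQEIRTEIGDIREQ
MTEVSLKATPAEDLAQSIDTISKKIKTQ
VDEVKDKVGSNEDLIQKIKTKIVGIATQ
VAEVKDKRTSNKGEIQDLAQEILNIQTQ
VNNVQNKAAVNEGLIAKIRKKERRIEPN
VNEVADKATSNSGTISDIRAKIKEIQVE
VNPLEQKANSNEPEISKIREKIDDIQPQ
=abcdefgabcdefgabcdefgabcdefg
>synthetic_block_06
LTTLKGKVVDNDDKNTAVAETQELMKQS
VDKLKGKRVAMDDLLSKVIDRARLAKQR
LKVLKPKRLSNDHQARGVLEQIRDMAQS
EQTLLDKRVSLDHENTSVKNRAQSLITS
LVTLAGNRSNNKHQITQVKPQAVSVKQS
LVTLRGSRVTVDHKLTQVKQQARLMKRR
LNTLKNERVKMDHKNTQVKTQLREMKQS
LQKIKTSLVSNDGKNTSVEEQVRLFKTS
=abcdefgabcdefgabcdefgabcdefg
>synthetic_block_07
ELEPDLKTELDDEKTEVATKTNDIHSLK
GEEPQLKETLQTRKRELNTLENQIKEAD
EKEKDLQETLSARKEEVAEIETLIKDLK
NLEPELTDTLTTRRREVATAEKKIPKLN
DLLDKLLKEFSLRKQELETSENTIKKAD
ELEPHLKLTLTSREENVQTSEKLLKKLK
ELEPSVAESLQARKTEVPTSQSLIRRLT
DLEQKLETTASARKTEVDDSEELIKKLD
=fgabcdefgabcdefgabcdefgabcde
>synthetic_block_08
EKALPKAQNLKNKFKHIKRELTGLAKEA
GDADDLAGPREAKLGTLATELTRQIEQA
GKADDKLQNLENKVNEIERDLTKQANEV
EEIDRKARNIKAKLVGLKRSLTELQELN
SKAQDRATEIDSELTTIKAELQKLEDQV
GKIDGKADSLAAELPAIKRELRQLEDQE
GQANDDAQSEKSKLNTIKAELTSIAVIV
GKMDKDAQSFENASNSIETNLASLAETV
=bcdefgabcdefgabcdefgabcdefga
>synthetic_block_09
QHLKAAQDELSDSLSEAKKELQHLETRV
QVLRAKLNGLKPSLSEAQSEVKNLKTRV
QSLSANEQKSKNSVGPAAQKFVQVATRS
KGLIGNIKGVAKNLDEAESESSNLEKLV
SSLKNKVNALQTSLSEAASELGQLDNRV
DSLKAKQNDLRDQLDEVESEADNLRNRV
RDKINKQHGLRDSLSQADKELRNLDQRV
NTLIDKQTHLLKLLSEVRKELQNLRTRV
=bcdefgabcdefgabcdefgabcdefga
>synthetic_block_10
QVLKEKSTNLKLDIVDLLSKLDTLDNKF
QLLDSKSGNMQREIKTLLRKEDVLDSKF
ESIQKKSNNLTDEIAEALSELDVLDREF
DELDSESTNADLEIPNLESKLTQLDDLL
ASLESKSNEKTLEIVNLLSELDVLDNKL
EDLDSDSNSLTSEIQNLLSKNDTLARQF
ESLDSKSSGFAARIVRLDQKLDRLDGKF
LDLETKSTNLTNLIDQLLSKLDVLTNEF
=bcdefgabcdefgabcdefgabcdefga
>synthetic_block_11
ASDAKHKEDSEKTAQQRLTDKRNSKDHI
QTENKQEEQQEDSATQELVDKEDEKKTI
AGNAKAVENQEDKAATEEVGLKDNKKNI
ATKARKVEAKEDTAAQELVDRKDRKGAI
AEDAKKLEDQEKKAQDALNEKKDDKDKV
QDDAKKVDDQEDNADERLQEEKSSKHNI
KTDAKKAADQESQAKQALTDKKRSKKTI
ETEAKNVEDEEETAQQRLNDKKDSKDDI
=efgabcdefgabcdefgabcdefgabcd
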