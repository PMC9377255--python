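>rep_L1_1
EAYMLKMLHMQTLKMFSTPMLSHETRVNRISFFINCPCETESKHKFKYDNPPWTKDAPNCGLAYTKFGHQ
WYCVWGPGTLSFAEAWNAGSVYPKQRLMDFGLCCWNMYMTNTEHHTIWYPFIEHGLLSHMNAFKSLDLKY
IFSPPLRTVKRSEHFTVYPERMYYVLMVIWLQDKKIKALDTLEGRNTVDNAFYHGNVEETVARAHQPEYG
LWYFEKYYNQVSRGCKEMMSYGQNFRHTRMQCNEHYCQKMPTIVYPLAHAKFQQFEWQRLGTAWILKECK
ECRAPSVYINICMPTCMIQASEPNMDKVNVWQCWHFSIPATTHWHENIQVFYNFNRENQWQDVAGIRTTT
FDVREASMRATCVLRLVIFKFTKRNWAFRVIREYQEDVKHQFAFYEYVESAPIIMTPCFCMHYTQARQGL
HIHGYLEFSDSRYHAFH
>rep_L1_2
ECDALKDLHVQMLTMFLTDMLWHETRVKRAVFFTNCPCPTESIPKFKYDNPPWTKDAPNCGLTYTKHKHK
WYCVWGPGTLSFAEAWNANSTCSSQFNMDFGLCCWNMYWTNDEHHTCWYPFIEHGLLSHMNAFKSLMGKY
IMSPPLRTVKHKPKFTVYLERMYYVLMVIWLQDKEIKALDTLEIRLTVSNAFYHGNVESTVAAAPRDEYG
LWPFEETYMQVSFGCKEMMSYGQHMRWTRRQCNEHWCFKQATIVYPLAHEKFQQFFWPRLGTTWILKECK
FCWAPSVYDNICIVTDRIRASPPNMDKVNVWICWHKYCLATDHWHENIQVFYNFNRENQWQDSAGCRRTT
QCCRHASMEATKLSILVIRKFTKRNWADMVKLKYQEDVIGTIGKYEYVESAWPIATPNFEMHYTQARRGL
HEHGYLCFSDSMYIAFH
>rep_L1_3
ECSMLATLHMQTLYMLSTDMQLHETRVNRISFFINCLCGTESIPKFKYDNPPWTKDAPNCGLAYFKHFHQ
WYCVVLPGTPSFAEAWNQGFHCTKQFNMQFGLCCWNMYMFNDEHHTCWYPFIEHGLLSHMNAFKSLMLKY
IFSPNLTTVKHSPKFYVAPKRMYYVLMVIWLQSKEIKALDTKEIENTVSNAFDHGNMEETVAAAYRPEYG
LWPQEETYMQVSPGCKEMMSYGQHFRWTSRQCCEHYYNKWPTIVYPLAHDKFQAFEWPRLGTAWILKECK
ESWAPSVYDNTCAPTCKIQASPPWMDKVNPWAIWHYSFPATDHWHENIQVFYNFNRENQWQDSLGIERTT
QDVRDASMRATCVSILVVQGFTKRNWACRVILKYQEDSIDAQGFYEYVESAYRIFVPCFECHYTQLYRGL
HEHGYLDPSDSRQHKFH
>rep_mL1_1
RKSSHKCKHGWTRNRMRTANVAMNDRLNHINSCENCPKFQREIQHYKYDNPPWTAIKDSCGFWMHGNQHD
TEEVWRFHGQSFAEAWNSGSTACRPGCMAGLHLLFNDPNVKYNTYFRGAFLDWSHSAHSGVIWNNNVLTS
ALVIIYRSYQTRMYYVLMIIWGQFCTYLAGRWLKMDFHLMQCFEYGNFCIWDTAAENGIYGAKMFCEMSS
MFIRGCKEMMSEGRHLVWFKRHCTSEPDNKDLLPIKPLTYIRAEQKNICAAGEAWILKECKECDAVSKIM
NDLMRADKTCICNEHLDKCNKDFPFTAFYDRHLCVVVHIQVFYNFNWFIVAHDSAAKDRPMVTKCDRLAV
EIKVNHTVIAKFTKRNWAQLFWHQMQSAEWQKMVEGEMREKLTMWDKPMCRMKCMKNWPYLTYNGCLALH
GNRVWWLR
>rep_mL1_2
RKSSVKCKHDWTRNRERTENVAIMDRLNFIHSVENCPKFQHEIQHYKYDNPPWQGIDTDNGTWWHGNEHD
TEEVWLYVTQSFAEAWNRGSTACRPTRQAGLHLLFNDPPHKHTTYGPGAFLDWSHSASSGVIVNNNVRTS
AKSIIYWLYQTRMYYVLMIIWGQFKKYTAIPWLKMFKHWMQCFEYGNTCTWDTDAEVGIVCAKEFPKMWS
MNIRGCKEMMSMGKHLVWFKRHCTEEPDNKDVLPKKPLTYIDAWIKNICAAIEAWILKECKECDAQSKIM
RDLMKALKTNICNEHLDKCNPDVPFTAGYDRTLCVVVHIQVFYNFNWDMVAHKKFQKFRHAVTNCDMLAV
TIKVNHTVIAKFTKRNWAQPFWHWMCSAEGQKMVEGEMMEICTVSMHPMSRMKCTKDTRGLTYASCLFLS
GGRFWALR
>rep_L2_1
CESNLKKCHMMRVTRSGYAGVDYVWHLNYIVEGKHEWPVPLRDPAFKYDNPPWRSSVPGCGFKGVYLRHS
KEAHQARGTASFAEAWNNPDTKHRKLMQDLKYYEEQGHMAWHWHFTRGHRYMWIFDCILPFIASSTIFRY
EQTRMYYVLMFILLQCDEIKYADTDHKRLHGMAAEFGGRHCYTNNENHYPRWDPTPFDITSHSFHAGCKE
MMSYMRHLKFNRFTCMSEYCDWMVLMKKNLDYEKRMQAEHTIMQISWILKECKEEYANSKIDRTSSPPLM
VGICWDHENIKHQSHCKVRKSHSVNWSVNTGMTKCWAVPATLFDEDYIQVFYNFNTPYGRHDSHGKDRIT
QDQRVPGMRPTQIVELELSRFTKRNWAFIWVFIMRAGGVQNQGQEWMVDKFPSEGTYMDAMIVTQSEWGF
ITSLDLQDCWFRKWTPY
>rep_L2_2
CESNLKKHDMMRVTIIGYANVDYVWQLNYIVQCKHEQPVPLRDPAFKYDNPPWRRSRPHCGSKYVYLRHP
LEKHWFRGTASFAEAWNNRDTKHIKLMQDLKYYKEQMHMGWHWHFTRGHRYHWIFDDILTTIASSTDFED
NPTRMYYVLMFILLQNKEIKGADTIPKRLHGMAWFFGGWPCYTQNVNAHPRAHNSPDDITSHWFHAGCKE
MMSYGRHLKFARFYCMNEYCDKMHLIKKNLHYEKRMHPEHTIMQTHWILKECKEEYTNSKIDDQSSNPNM
VQICWDHENIKHQSHCKVRKSHSVQDSVRKSMTKCWHVIATMSQELYIQVFYNFNMPYVRHESAGKDRIT
QDQRVPGMRPTMIWELRLSRFTKRNWAFTWVFSMTAGPVPAQGDEFMIEKFCHSGTYMDAAYYTQSETGT
ATCVDIRFPWFRKWTPY
>rep_L2_3
CESNLKKIHMSRVTRIQCNNCDYVWQLNYIVECKDEWPVPLRDDAFKYDNPPWQRSRPCCGSKYVNLWHF
CEKHCDRQTASFAEAWNNRFEKHRCLMQDLKYYSEKMHYAWHWGWTRGHRYMWIFDEALPTIASSTQIKD
YTTRMYYVLMFILLQNKEIKYADTPPKRLHGMAAFFGGWHCYTQVEWHYPRFDNTPFDITSHWFDAGCKE
MMSYGRHLKFDRFYGCNEYCDKMHLISKNWDYEKYWQAEHTIMQTHWILKECKEEYANSKWDDTLSVPNM
VQICWDHENIKHQSHCKVRKSHSVQWSKRTGYMNCWCVPAFLFDELYIQVFYNFNTPYVRHSMVGKDRIT
QDPRVPGMRPTQIVELELSRFTKRNWAFIDVFDMRAGGVQGQGQEFMCEKHCCEGTYDDAMKYTQSEDGT
SHCWDLHFPMFPKATPY
>rep_mL2_1
NPCNRKMTHKMALTRMATDNVDKMTPLGRIPNIAYWQFQPLCMCHCKYDNPPWTENTILCGWACRGMVFD
IPEVYMKGTQSFAEAWNNRKTSCAQGNEALCHLSCETPMAHKEMDMRWACYMVHEQDTICCEYQECEQAW
DQERMYYVLMMDWGQNWNAEAWDTWKCELHGMGADVGQPWCKTCAHERIAHYWAKSYYAQSQRFAMGCKE
MMSYGHGLFNGGRRWCLMKEAKAHLMTTGYCYLWCKQSDIWQCGTEWILKECKTCWAFSSTWSDVYFINK
LEVCFECAKPESRRQMDSVKAYSPHTTTTNATNFRVGNMQVFYNFNWAMVYHASIQERRNMQSWVDPYMG
GTSVNIVICSWFTKRNWAFLNLRRMQSVPGQCFGQDWMLAKWACTETWQQGVACKSDTDGPATAGYLKGH
MSGKDAIP
>rep_mL2_2
NPVNRKMTHDMWLTPMATDNVDYMGSLGRIPNCKYSQVQPLCFSHCKYDNPPWTENTPLCGNAYRGNVSD
TPEVYQKGTQSFAEAWNNRKTSCQKGVMALCHGSCEAYMAWWEVDMCWAKYMPHELDTLMCWYHECEDAW
DQERMYYVLMGDWGQNWNIEAWDTKKCELHYMGADWGQPWCMTCACSHIGHYWAKSYQQQEHREAMGCKE
MMSYGFGLRNGARRWCKDLQAKDHLMVTGNWYLWGKQSDILQCGTQWILKECKTDWAFSSIWSDVYFINK
LDVCFECAKPESRRQHDSKTAAPPLTTWTKATNFKVGNMQVFYNFNWTMVLHASTQTRRNMQVWRDPHNG
ATSVMKVICSWFTKRNWAFLWPRDIQCGPGQCFGHDWMLAKWACRETWINGVACMEDQDGPATRGYLGAH
FSCSDAIR
>rep_mL1_2_1
ECPCLPVMHWMQGHPGMTDNWDYHKGLNTIDARKMNPPWGLEQPHQKYDNPPWCNTKSHNAMAYNPVHHD
THEVTVKGWRSFAEAWNHGWRFGLGMMMVLQHKCMNGADIWWDHPWSGIMPKKRLLASYMPQDIKNEWTA
GVYFNFEHYQERMYYVLMCICGIAKEIFKMNTLQMKNECMMLCFGPVMYDSQIAYHWPEVGQPPFDEFSN
IADPGCKEMMSRNKQLAKFKRRCTAEMWFPDELHIKPLTYPYCMQCVHPQRNAAWILKECKGRYANNSVN
KHMPMYTYDHGTAYGMSDPEWVAFDTVEWCIPKTSNSSSQDFMVFNAQVFYNFNRQMWNHDNAGKEIIMT
IQSDILFITFPHARFVPSKFTKRNWAMQEWCWAWLGTGQRQPVYHRREFFTCCMHYQKLMKIKTAVHPLM
SQMHLFFHWHRYVAIK
>rep_mL1_2_2
ECYDLPCMHMMQGMPGMHDNWCYHKGVPRIVAIKMNPPWRLEQPHQKYDNPPWTLTKSHNAMGYNPVHHD
THEVQVKGWRSFAEAWNHGWRKCIIDMSVLFHKHENGWDIWEDPPWSGIMPKKRLLASYMIQDIYNEWKA
GVKEQFWHAQERMYYVLMDIHGIAKEIYKMYTLSDKNERMLLCFDPVMYDSQSAIHAPEYIPKPFQETSN
KLDFGCKEMMSYNRQLVKQKRRCTGEMINKDELHIKPLTYPYCMQCVHPLTNAHWILKECKGCCACNSVQ
MHMPMYEYDHCTDRGMSDPEWVVFSTEKWLIPKTSNASSNEFMVFNAQVFYNFNRVGWPGDSAGPEIIMT
IQFDQLFITFKHVIFVPSKFTKRNWAMQEWCWTQLGTGQREPTYHKGERFTCCMHYQELMKCTTLVHGLA
SQMWLFFHWHLYWAIK
>rep_NL_1
VCFNGLNTHSMTLCRMETDNHWPCARLNHLVNCTDCNPWGLKDETCKYDNPPWRFSCPQCGSATTGMWNY
MEEWPYKGKRSFAEAWNNPSTSCNKGNYDLKLCCENFCMMHSEHRTISSIIKYRPDMNCRGMPHSPTEFL
PQERMYYVLMMVKGCHKEIDIKDTLKMLRHGMSYFTISGHSCEMDIAACPEEGHEWYLEEMKATIGGCKE
MMSCYDMLCWFWDRCNHEFECYQGAWYQVAFLPKCIQFWIPRWGQHWILKECKEFPDDSKQECDMHCTGW
INISLMRMDSFMCIIYGYYVCPQTECAVLAIQVFYNFNFHMWAHDISGIRLITQYQEDPLERTFSVNIWL
YLKFTKRNWAMLNWQPIHILPSMYKSWFEVSEKFPPINTQMDGMNYCQLTYNFYSRAFHWYWKMWYWAER
>rep_NL_2
VCFNGLNPESYTLCPMGTDNHGPCARLNHLVNCTDCEPWGGKDPTCKYDNPPWTFSTPTCGSAGTKERFC
LEELPVKGKRSFAEAWNNPSGSCNKPNEDLKLCCENFQMMHSEHYNGSSIYKTRNDPNLRGMPHSATGDL
PQERMYYVLMMVQGCHSEMNIKDALKILRHGMSYFPISGHDRGMDDAHCDEAAMEWKLEEHKAMIIGCKE
MMSAGDMLCWLYDRCTHEYECQQGQPYTVIPWPKCIVFCVYRWGCHWILKECKESPCDSKAECIMDCMGW
INRSLVRMDYRMCIFYKTYLMTETECAVLAIQVFYNFNFHMWAHCISGQRHITQWTEDPLERTFSVNKWA
YSKFTKRNWAMLNGQWIFILPSDVKGWFEVSKKFPPVNTQMDGMKYIQLTRCFWSRGLWWTWQMWYWAER
>rep_NL_3
VCFNGLNPHFMVLCNMITDNHGPCARLNHCVNCGDCNWWGLKDSTCKYDNPPWTISCLQWGSAGTGEIFC
LEEWPGSGARSFAEAWNNPSTSCNKGNYDLKRCCENFCMMHSFHYTGASIYKHRPDPNLRGMPHSPTRDL
PQERMYYVLMMQKQCHKEIDCKRSLKMLAHVMSYFPISGHSRDDDIRHCPEEGMEIKLEEHMATIIGCKE
MMSAGDMICWFYDRCTHEYECLQGQDYIVLPWPMCIQFCIPVWGCHWILKECKESPDDSKAECDMHCAGY
ITQSLMRMDIHMRIIYKTYVMRETECAVLATQVFYNFNQHMWGHCISLIKLITRWQEDPDERTFSVSKWL
YTKFTKRNWAQLNMQFIHILPQDVFGWFEVSEKFPPVNMQADWMKRCQHTRNFYSRGLHWYWQMWFWAER
>rep_FMN_1
MSWREAMEHECILTKKFGDNIDYVNFLNGTVMCKRCWPWGLGRVKWKYDNPPWTSTCPIAGHAIEFLRCD
THDVCDDLSMSFAEAWNKISKYCQIIGVDLVALCENMHMAWECFYFCFAYTKYIASQVDRNMAHAYIFQR
YIERMYYVLMWNVLQNKTDGAADHFWYILNGGGHFCRPNMFHMKAAVHEPGLYADLFANTSDSLKRGCKE
MMSWGRMWHMCIQRITWEYCAIYHLHKCFLCYLCNYQFEHPRIGDCWILKECKIPWAHSKIQNDMPPDPK
LSIMFMNMDRVNGSIRKMSCLPAKMQWVPLIQVFYNFNWNTAHIDSGVNIRYEQPYVPILQRQQHGTPTF
ISYFTKRNWAHQWWTWPEKYFKHKDGWQEMEECFPDAVCDMSGMKMTQDNRGEKLAGYLCAHKSYYWDDH
HMNIMEFLIFEKSWWYFWEAPNRWFDCWTGVESEDAHHHRPAFSYCCQNARTEWCVELYSKINYKNRSDE
LKKSGPQDDHRWHVWTFYSWWWPYQYDCDTVRTLAYWVTRMYLAAKMFNY
>rep_FMN_2
ESWDEAMPHDLINTKQFHDNHDFVNKLNKIQMCKSCWPWGSGRNHWKYDNPPWTSSCPQAGYACIFLRHD
LIWVCDDLSMSFAEAWNHISKYCQIKPPDLVALCANMHMAWEEFYFCIAQTDYIASCVDRNMAHAPMFHL
LCERMYYVLMWPVQQNKLRGARDHIWYILLGHGHFCRCNMFGMPDAVHHPEYYRDIFAETSDSGKFGCKE
MMSWGYEWVQCIQRITWEYCAWYHLHKCALCYLKTYFFEHPRIGDFWILKECKIPWYHSKIQNDMPPDPK
LCYMFMNMDIVNESDRKMLVLPATEQRLKKIQVFYNFNWNTENIDSGVLIRMIQSYVPDKKRQTGGGPTP
GSCFTKRNWAHQWWTWPEKYFGHKYILQEMEEKFPDDVCDPEGMKMTQDNRGLKLAGYLCFHLSQYWNDL
HAGIMEVLIFEKSWWQHWEAPNRLMDCWTGWLSDTAHEHRMAISYCCRNIRHEWHVELYSLINYKNRSAE
LKKSGPQDDHNAPVHSFDGFWWPYQYDLHTVRTLAYPQTQMVLEAKMFNY
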