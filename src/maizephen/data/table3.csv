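variety,site,observed_days,predicted_days,se_days
VE-200,Kiboswa,56,52,3
VE-201,Kiboswa,56,56,1
VE-202,Kiboswa,61,59,3
VE-203,Kiboswa,66,62,2
VE-204,Kiboswa,59,55,3
VE-205,Kiboswa,58,57,2
VE-206,Kiboswa,61,63,2
VE-207,Kiboswa,61,64,3
VE-208,Kiboswa,59,56,3
VE-209,Kiboswa,61,60,1
VE-210,Kiboswa,61,60,2
VE-211,Kiboswa,59,58,3
VE-212,Kiboswa,69,65,2
VE-213,Kiboswa,59,56,3
VE-214,Kiboswa,49,50,1
VE-215,Kiboswa,61,59,3
VE-216,Kiboswa,58,58,1
VE-217,Kiboswa,58,57,1
VE-218,Kiboswa,56,57,2
VE-219,Kiboswa,58,56,3
VE-220,Kiboswa,48,49,1
VE-221,Kiboswa,59,59,1
VE-200,Nyahera,73,70,3
VE-201,Nyahera,73,72,3
VE-202,Nyahera,73,71,2
VE-203,Nyahera,79,75,3
VE-204,Nyahera,73,73,1
VE-205,Nyahera,72,70,1
VE-206,Nyahera,74,75,1
VE-207,Nyahera,74,72,2
VE-208,Nyahera,74,71,2
VE-209,Nyahera,74,71,3
VE-210,Nyahera,74,74,1
VE-211,Nyahera,73,73,1
VE-212,Nyahera,79,79,2
VE-213,Nyahera,74,74,1
VE-214,Nyahera,73,72,2
VE-215,Nyahera,73,72,1
VE-216,Nyahera,73,74,1
VE-217,Nyahera,73,72,2
VE-218,Nyahera,73,74,2
VE-219,Nyahera,73,73,1
VE-220,Nyahera,70,71,2
VE-221,Nyahera,73,70,3
VE-200,Vihiga,79,78,2
VE-201,Vihiga,76,75,2
VE-202,Vihiga,78,78,1
VE-203,Vihiga,77,75,3
VE-204,Vihiga,75,74,2
VE-205,Vihiga,77,76,2
VE-206,Vihiga,78,77,1
VE-207,Vihiga,76,77,2
VE-208,Vihiga,75,75,1
VE-209,Vihiga,76,74,3
VE-210,Vihiga,79,79,1
VE-211,Vihiga,76,74,3
VE-212,Vihiga,80,81,2
VE-213,Vihiga,75,75,2
VE-214,Vihiga,78,77,1
VE-215,Vihiga,75,75,1
VE-216,Vihiga,78,78,1
VE-217,Vihiga,79,80,2
VE-218,Vihiga,73,70,3
VE-219,Vihiga,77,78,2
VE-220,Vihiga,75,74,2
VE-221,Vihiga,75,74,2
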